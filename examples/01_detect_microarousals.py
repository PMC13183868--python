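"""Detect NREM micro-arousals in a synthetic recording and score recovery.

Generates a 2-h recording with known planted muscle bursts, runs the
EMG-based detector, and compares the output against the ground truth.
"""

import numpy as np

from microarousal import SyntheticConfig, detect_microarousals, generate_recording

bundle = generate_recording(SyntheticConfig(seed=1, duration_s=7200.0))
events = detect_microarousals(bundle.emg, bundle.hyp)
expected = bundle.truth.expected_events()

print(f"planted muscle events: {len(bundle.truth.bursts)} "
      f"({len(expected)} satisfy the inclusion rules)")
print(f"detected NREM micro-arousals: {len(events)}")

matched, errors = 0, []
used = set()
for e in expected:
    for i, d in enumerate(events):
        if i not in used and abs(d.onset - e.onset) < 1.0:
            used.add(i)
            matched += 1
            errors.append(abs(d.onset - e.onset))
            break

print(f"sensitivity: {100 * matched / len(expected):.1f}%  "
      f"precision: {100 * matched / len(events):.1f}%  "
      f"mean onset error: {np.mean(errors) * 1000:.0f} ms")
print("\nfirst five events (onset s, duration s, envelope peak):")
for e in events[:5]:
    print(f"  {e.onset:8.2f}  {e.duration:5.2f}  {e.peak_amplitude:.3f}")

# Sensitivity/precision near 100% mean the 2xSD envelope threshold plus the
# merge/exclusion rules isolate exactly the planted brief muscle bursts that
# are surrounded by undisturbed NREM sleep; onset error ~0.1 s reflects the
# envelope smoothing windows.
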