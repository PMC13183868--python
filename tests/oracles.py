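"""Independent brute-force reference implementations used as oracles.

Deliberately naive code paths (per-epoch scans, repeated pairwise passes,
fine-grained time sampling) kept separate from the library so tests compare
two genuinely different implementations of the same rules.
"""

from __future__ import annotations

import numpy as np

from microarousal.core import Interval
from microarousal.hypnogram import Hypnogram


def episodes_by_scan(hyp: Hypnogram, state: str):
    """Per-epoch scan for maximal runs of a state."""
    out = []
    cur_start = None
    for i, lab in enumerate(hyp.labels):
        t = hyp.start_time + i * hyp.epoch_s
        if lab == state:
            if cur_start is None:
                cur_start = t
        else:
            if cur_start is not None:
                out.append(Interval(cur_start, t - cur_start))
                cur_start = None
    if cur_start is not None:
        out.append(Interval(cur_start, hyp.end_time - cur_start))
    return out


def fraction_by_sampling(hyp: Hypnogram, window: Interval, state: str, dt: float = 0.001):
    """Time-in-state by dense midpoint sampling at resolution ``dt``."""
    n = int(round(window.duration / dt))
    t = window.onset + (np.arange(n) + 0.5) * dt
    inside = (t >= hyp.start_time) & (t < hyp.end_time)
    idx = np.floor((t[inside] - hyp.start_time) / hyp.epoch_s).astype(int)
    hits = np.count_nonzero(hyp.labels[idx] == state)
    return hits * dt / window.duration


def peaks_by_scan(samples: np.ndarray, fs: float, threshold: float):
    """Supra-threshold runs found one sample at a time."""
    out = []
    start = None
    for i, v in enumerate(samples):
        if v > threshold and start is None:
            start = i
        elif v <= threshold and start is not None:
            out.append(Interval(start / fs, (i - start) / fs))
            start = None
    if start is not None:
        out.append(Interval(start / fs, (len(samples) - start) / fs))
    return out


def _state_at(hyp: Hypnogram, t: float):
    for i, lab in enumerate(hyp.labels):
        a = hyp.start_time + i * hyp.epoch_s
        if a <= t < a + hyp.epoch_s:
            return lab
    return None


def _window_all_nrem(hyp: Hypnogram, lo: float, hi: float) -> bool:
    if lo < hyp.start_time or hi > hyp.end_time:
        return False
    for ep in episodes_by_scan(hyp, "N"):
        if ep.onset <= lo and hi <= ep.offset:
            return True
    return False


def postprocess_by_rules(candidates, hyp: Hypnogram, cfg):
    """Exhaustive rule-by-rule re-implementation of event post-processing.

    Merging is done by repeated full passes until a fixed point; every other
    rule is applied by explicit scanning.  Returns plain (onset, offset)
    tuples.
    """
    # rule 1: midpoint inside NREM
    events = []
    for iv in candidates:
        mid = iv.onset + iv.duration / 2.0
        if _state_at(hyp, mid) == "N":
            events.append((iv.onset, iv.onset + iv.duration))

    # rule 2: merge until fixed point
    changed = True
    while changed:
        changed = False
        for i in range(len(events) - 1):
            a, b = events[i], events[i + 1]
            if b[0] - a[1] < cfg.merge_gap_s:
                events[i : i + 2] = [(a[0], max(a[1], b[1]))]
                changed = True
                break

    # rule 3: neighbour exclusion, simultaneous marking
    doomed = set()
    for i in range(len(events)):
        for j in range(len(events)):
            if i == j:
                continue
            gap = max(events[j][0] - events[i][1], events[i][0] - events[j][1])
            if gap < cfg.exclusion_gap_s:
                doomed.add(i)
    events = [e for k, e in enumerate(events) if k not in doomed]

    # rule 4: duration cap
    events = [e for e in events if e[1] - e[0] <= cfg.max_duration_s]

    # rule 5: REM-follow exclusion
    rem_eps = episodes_by_scan(hyp, "R")
    kept = []
    for e in events:
        follows_rem = any(
            ep.offset <= e[0] < ep.offset + cfg.rem_follow_window_s for ep in rem_eps
        )
        if not follows_rem:
            kept.append(e)
    events = kept

    # rule 6: undisturbed NREM flanks
    events = [
        e
        for e in events
        if _window_all_nrem(hyp, e[0] - cfg.flank_nrem_s, e[0])
        and _window_all_nrem(hyp, e[1], e[1] + cfg.flank_nrem_s)
    ]
    return events


def rescore_by_scan(hyp: Hypnogram, max_intrusion_s: float = 11.0) -> Hypnogram:
    """Rescoring by explicit neighbourhood inspection of every epoch run."""
    labels = list(hyp.labels)
    n = len(labels)
    i = 0
    out = list(labels)
    while i < n:
        j = i
        while j < n and (labels[j] != "N") == (labels[i] != "N"):
            j += 1
        if labels[i] != "N":
            left_n = i > 0 and labels[i - 1] == "N"
            right_n = j < n and labels[j] == "N"
            if left_n and right_n and (j - i) * hyp.epoch_s < max_intrusion_s:
                for k in range(i, j):
                    out[k] = "N"
        i = j
    return Hypnogram(np.array(out), hyp.epoch_s, hyp.start_time)
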