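"""Detector unit tests: envelope, thresholding, rule post-processing and
the three detection variants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from microarousal import (
    DetectionConfig,
    Hypnogram,
    Interval,
    SignalTrace,
    average_rectified_emg,
    detect_emg_peaks,
    detect_microarousals,
    detect_rem_terminating_mas,
    detect_wake_transitions,
    postprocess_events,
    rectify_emg,
)
from microarousal.ma_detect import Envelope
from microarousal.synthetic import SyntheticConfig, generate_emg, generate_hypnogram, _streams

from .oracles import peaks_by_scan, postprocess_by_rules

FS = 256.0
CFG = DetectionConfig(median_filter_order_samples=2000)  # short traces in unit tests


def H(labels, epoch_s=4.0):
    return Hypnogram(np.array(list(labels)), epoch_s=epoch_s)


class TestRectifyEMG:
    def test_zero_signal_gives_zero_envelope(self):
        emg = SignalTrace(np.zeros(5000), FS)
        env = rectify_emg(emg, CFG)
        assert env.samples.shape == (5000,)
        assert np.allclose(env.samples, 0.0)

    def test_dc_offset_invariance(self, rng):
        x = rng.standard_normal(6000)
        a = rectify_emg(SignalTrace(x, FS), CFG).samples
        b = rectify_emg(SignalTrace(x + 37.0, FS), CFG).samples
        assert np.allclose(a, b, atol=1e-9)

    def test_burst_elevates_envelope(self, rng):
        x = rng.standard_normal(int(60 * FS))
        seg = slice(int(30 * FS), int(32 * FS))
        x[seg] *= 10.0
        env = rectify_emg(SignalTrace(x, FS), CFG).samples
        inside = env[seg].max()
        outside = np.median(env[: int(25 * FS)])
        # elevation well above surrounding envelope level
        assert inside > 5.0 * max(outside, np.median(env))
        # and consistent with a direct per-window SD estimate (~10x baseline)
        direct_sd = x[seg].std()
        assert inside == pytest.approx(direct_sd, rel=0.5)

    def test_too_short_trace(self):
        with pytest.raises(ValueError, match="too short"):
            rectify_emg(SignalTrace(np.zeros(100), FS), CFG)

    def test_exact_vs_strided_median_agree(self, rng):
        x = rng.standard_normal(4000)
        exact = rectify_emg(SignalTrace(x, FS), DetectionConfig(
            median_filter_order_samples=1000, median_stride=1))
        strided = rectify_emg(SignalTrace(x, FS), DetectionConfig(
            median_filter_order_samples=1000, median_stride=64))
        scale = exact.samples.std()
        assert np.allclose(exact.samples, strided.samples, atol=0.15 * scale)


class TestDetectPeaks:
    def test_constant_envelope_yields_nothing(self):
        env = Envelope(np.full(4000, 3.0), FS)
        assert detect_emg_peaks(env, H("N" * 10), CFG) == []

    def test_rectangular_excursion(self):
        x = np.zeros(int(40 * FS))
        x[int(10 * FS) : int(12 * FS)] = 5.0
        env = Envelope(x, FS)
        peaks = detect_emg_peaks(env, H("N" * 10), CFG)
        assert len(peaks) == 1
        assert peaks[0].onset == pytest.approx(10.0, abs=1 / FS)
        assert peaks[0].duration == pytest.approx(2.0, abs=2 / FS)

    def test_matches_per_sample_scan(self, rng):
        x = np.abs(rng.standard_normal(2000))
        env = Envelope(x, FS)
        hyp = H("N" * 2)
        peaks = detect_emg_peaks(env, hyp, CFG)
        thr = env.threshold
        assert peaks == peaks_by_scan(x, FS, thr)

    def test_no_nrem_errors(self):
        env = Envelope(np.abs(np.random.default_rng(0).standard_normal(2000)), FS)
        with pytest.raises(ValueError, match="no NREM"):
            detect_emg_peaks(env, H("WW"), CFG)


def wide_nrem(n_epochs=60):
    return H("N" * n_epochs)


class TestPostprocess:
    def test_merge_rule(self):
        # two peaks 6 s apart merge into one 9-s event, kept
        cands = [Interval(100.0, 2.0), Interval(108.0, 1.0)]
        out = postprocess_events(cands, wide_nrem(), CFG)
        assert len(out) == 1
        assert out[0].onset == 100.0
        assert out[0].duration == pytest.approx(9.0)

    def test_exclusion_rule_drops_both(self):
        # gap 13 s: unmerged (>= 10) but excluded (< 20)
        cands = [Interval(100.0, 2.0), Interval(115.0, 2.0)]
        out = postprocess_events(cands, wide_nrem(), CFG)
        assert len(out) == 0

    def test_duration_cap(self):
        # merged event of 11 s is excluded
        cands = [Interval(100.0, 5.0), Interval(107.0, 4.0)]
        out = postprocess_events(cands, wide_nrem(), CFG)
        assert len(out) == 0

    def test_outside_nrem_dropped(self):
        hyp = H("W" * 30 + "N" * 30)
        cands = [Interval(20.0, 2.0), Interval(150.0, 2.0)]
        out = postprocess_events(cands, hyp, CFG)
        assert [e.onset for e in out] == [150.0]

    def test_rem_follow_excluded(self):
        # REM ends at 120 s; peaks at 121 s (inside 4-s window) and 160 s
        hyp = H("N" * 15 + "R" * 15 + "N" * 30)
        cands = [Interval(121.0, 2.0), Interval(160.0, 2.0)]
        out = postprocess_events(cands, hyp, CFG)
        assert [e.onset for e in out] == [160.0]

    def test_flank_requirement(self):
        # event 10 s after a wake episode lacks the 20-s NREM pre-flank
        hyp = H("W" * 10 + "N" * 50)
        cands = [Interval(50.0, 2.0), Interval(120.0, 2.0)]
        out = postprocess_events(cands, hyp, CFG)
        assert [e.onset for e in out] == [120.0]

    def test_unsorted_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            postprocess_events([Interval(10.0, 1.0), Interval(5.0, 1.0)], wide_nrem(), CFG)

    @given(
        st.lists(
            st.tuples(
                st.floats(min_value=0.0, max_value=230.0),
                st.floats(min_value=0.1, max_value=15.0),
            ),
            max_size=20,
        ),
        st.lists(st.sampled_from("WNR"), min_size=60, max_size=70),
    )
    @settings(max_examples=300, deadline=None)
    def test_matches_brute_force_oracle(self, raw, labels):
        # build sorted, non-overlapping candidates
        raw.sort()
        cands = []
        for onset, dur in raw:
            if cands and onset < cands[-1].offset:
                onset = cands[-1].offset + 0.01
            cands.append(Interval(onset, dur))
        hyp = H(labels)
        got = postprocess_events(cands, hyp, CFG)
        ref = postprocess_by_rules(cands, hyp, CFG)
        assert [(e.onset, e.offset) for e in got] == pytest.approx(ref)


class TestEndToEnd:
    def _bundle(self, seed=7, duration=1800.0, **kw):
        cfg = SyntheticConfig(seed=seed, duration_s=duration, **kw)
        streams = _streams(cfg.seed)
        hyp = generate_hypnogram(cfg, streams["hypnogram"])
        emg, truth = generate_emg(hyp, cfg, streams["emg"])
        return cfg, hyp, emg, truth

    def test_planted_bursts_recovered(self):
        cfg, hyp, emg, truth = self._bundle()
        events = detect_microarousals(emg, hyp)
        expected = truth.expected_events()
        assert len(expected) > 0
        matched, errors = 0, []
        for e in expected:
            hits = [d for d in events if abs(d.onset - e.onset) < 1.0]
            if hits:
                matched += 1
                errors.append(abs(hits[0].onset - e.onset))
        assert matched >= 0.9 * len(expected)
        assert np.mean(errors) <= 0.25

    def test_no_events_without_nrem_bursts(self):
        # all-wake recording: no NREM -> detector refuses (no threshold basis)
        cfg = SyntheticConfig(seed=3, duration_s=1200.0,
                              transitions={"W": {"N": 0.0, "R": 0.0},
                                           "N": {"W": 1.0, "R": 0.0},
                                           "R": {"W": 1.0, "N": 0.0}})
        streams = _streams(cfg.seed)
        hyp = generate_hypnogram(cfg, streams["hypnogram"])
        emg, _ = generate_emg(hyp, cfg, streams["emg"])
        with pytest.raises(ValueError, match="no NREM"):
            detect_microarousals(emg, hyp)

    def test_amplitude_rescaling_invariance(self):
        cfg, hyp, emg, truth = self._bundle(seed=11)
        a = detect_microarousals(emg, hyp)
        scaled = SignalTrace(emg.samples * 7.3, emg.sampling_rate)
        b = detect_microarousals(scaled, hyp)
        assert [(e.onset, e.duration) for e in a] == [(e.onset, e.duration) for e in b]

    def test_determinism(self):
        cfg, hyp, emg, _ = self._bundle(seed=5)
        a = detect_microarousals(emg, hyp)
        b = detect_microarousals(emg, hyp)
        assert [(e.onset, e.duration, e.peak_amplitude) for e in a] == [
            (e.onset, e.duration, e.peak_amplitude) for e in b
        ]


class TestVariants:
    def _rem_recording(self, burst_after_rem_s):
        """All-NREM recording with one REM episode and one burst planted a
        fixed delay after REM end."""
        rng = np.random.default_rng(99)
        labels = ["N"] * 150 + ["R"] * 30 + ["N"] * 150
        hyp = H(labels)
        fs = FS
        n = int(hyp.duration_s * fs)
        x = rng.standard_normal(n) * 0.15
        rem_end = 180 * 4.0
        t0 = rem_end + burst_after_rem_s
        i0, i1 = int(t0 * fs), int((t0 + 2.0) * fs)
        x[i0:i1] += rng.standard_normal(i1 - i0) * 0.9
        return SignalTrace(x, fs), hyp, t0

    def test_burst_inside_window_detected(self):
        emg, hyp, t0 = self._rem_recording(2.0)
        out = detect_rem_terminating_mas(emg, hyp, CFG)
        assert len(out) == 1
        assert out[0].kind == "rem_ma"
        assert abs(out[0].onset - t0) < 0.5

    def test_burst_outside_window_ignored(self):
        emg, hyp, _ = self._rem_recording(6.0)
        assert len(detect_rem_terminating_mas(emg, hyp, CFG)) == 0

    def test_all_nrem_recording_empty(self, rng):
        hyp = H("N" * 300)
        emg = SignalTrace(rng.standard_normal(int(hyp.duration_s * FS)) * 0.15, FS)
        assert len(detect_rem_terminating_mas(emg, hyp, CFG)) == 0

    def test_threshold_override_used(self):
        emg, hyp, t0 = self._rem_recording(2.0)
        # absurdly high manual threshold suppresses the detection
        out = detect_rem_terminating_mas(emg, hyp, CFG, threshold_override=1e9)
        assert len(out) == 0

    def _wake_transition_recording(self, bout_s):
        rng = np.random.default_rng(7)
        labels = ["N"] * 150 + ["W"] * 60 + ["N"] * 150
        hyp = H(labels)
        n = int(hyp.duration_s * FS)
        x = rng.standard_normal(n) * 0.15
        # scattered ordinary micro-arousal bursts give the NREM envelope a
        # realistic SD (the 2x-SD threshold is meaningless on pure noise)
        for tb in (60.0, 150.0, 280.0, 400.0, 980.0, 1100.0, 1250.0, 1380.0):
            j0, j1 = int(tb * FS), int((tb + 2.0) * FS)
            x[j0:j1] += rng.standard_normal(j1 - j0) * 0.9
        t0 = 150 * 4.0 - 1.0  # bout starts 1 s before the wake scoring
        # phasic muscle activity: 1-s movements every 4 s (as in real wake
        # EMG); the merge rule stitches them into one bout
        t = t0
        while t < t0 + bout_s:
            i0, i1 = int(t * FS), int(min(t + 1.0, t0 + bout_s) * FS)
            x[i0:i1] += rng.standard_normal(i1 - i0) * 1.2
            t += 4.0
        return SignalTrace(x, FS), hyp, t0

    def test_long_bout_is_wake_transition(self):
        emg, hyp, t0 = self._wake_transition_recording(30.0)
        out = detect_wake_transitions(emg, hyp, CFG)
        assert len(out) == 1
        assert out[0].kind == "wake_transition"
        assert out[0].duration > 20.0

    def test_short_bout_ignored(self):
        emg, hyp, _ = self._wake_transition_recording(5.0)
        assert len(detect_wake_transitions(emg, hyp, CFG)) == 0


class TestAverageRectifiedEMG:
    def test_single_event_mean_is_segment(self, rng):
        env = Envelope(np.abs(rng.standard_normal(int(120 * FS))), FS)
        from microarousal.core import Event, EventSet

        ev = EventSet([Event(60.0, 2.0)])
        t, mean, sem = average_rectified_emg(env, ev, pre_s=5.0, post_s=5.0)
        i0 = int(55.0 * FS)
        assert np.allclose(mean, env.samples[i0 : i0 + len(t)])
        assert np.all(sem == 0.0)

    def test_identical_events_zero_sem(self):
        fs = FS
        x = np.zeros(int(300 * fs))
        for t0 in (60.0, 180.0):
            i0, i1 = int(t0 * fs), int((t0 + 2) * fs)
            x[i0:i1] = 4.0
        env = Envelope(x, fs)
        from microarousal.core import Event, EventSet

        ev = EventSet([Event(60.0, 2.0), Event(180.0, 2.0)])
        t, mean, sem = average_rectified_emg(env, ev, pre_s=5.0, post_s=5.0)
        assert np.allclose(sem, 0.0)
        assert mean[(t >= 0.5) & (t < 1.5)].mean() == pytest.approx(4.0)

    def test_empty_events_error(self):
        from microarousal.core import EventSet

        env = Envelope(np.zeros(1000), FS)
        with pytest.raises(ValueError, match="no events"):
            average_rectified_emg(env, EventSet([]), 1.0, 1.0)
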