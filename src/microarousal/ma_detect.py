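"""Automated EMG-based detection of NREM sleep micro-arousals.

The detector works as a post-processing step on recordings that have already
been sleep-scored.  Pipeline:

1. brief wake/REM intrusions (< 11 s) inside NREM are rescored as NREM;
2. the EMG is rectified into a tonus envelope (moving SD, moving mean,
   running-median baseline subtraction);
3. supra-threshold envelope peaks are extracted at 2x the envelope SD over
   NREM sleep;
4. peaks are merged/excluded by the printed rules: outside-NREM peaks are
   dropped, peaks < 10 s apart are combined, events within 20 s of each
   other are omitted, events longer than 10 s are excluded, events within
   4 s after a REM-sleep termination are excluded, and each event must be
   flanked by >= 20 s of uninterrupted NREM on both sides.

Two variants reuse the same machinery: detection of micro-arousals that
terminate REM sleep (onset within 4 s after a REM episode end, optional
per-recording manual threshold) and detection of sleep-to-wake transitions
(muscle-activity bouts longer than 20 s starting from NREM).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import uniform_filter1d

from .core import (
    Event,
    EventSet,
    Interval,
    NREM_MA,
    REM_MA,
    SignalTrace,
    WAKE_TRANSITION,
    merge_intervals,
)
from .hypnogram import Hypnogram, NREM, REM, rescore_short_intrusions, state_episodes

__all__ = [
    "DetectionConfig",
    "Envelope",
    "rectify_emg",
    "detect_emg_peaks",
    "postprocess_events",
    "detect_microarousals",
    "detect_rem_terminating_mas",
    "detect_wake_transitions",
    "average_rectified_emg",
]


@dataclass(frozen=True)
class DetectionConfig:
    """All detector constants in one auditable place.

    Defaults implement the published rules: threshold at 2x the envelope SD,
    peaks < 10 s apart combined, events within 20 s of each other omitted,
    events longer than 10 s excluded, >= 20 s of NREM required on both
    flanks, wake/REM intrusions < 11 s rescored, a 10000-sample running
    median as slow envelope baseline, REM-terminating arousals accepted
    within 4 s after REM end, and wake transitions defined as bouts > 20 s.

    ``envelope_sd_window_s`` and ``envelope_mean_window_s`` (the moving-SD
    and moving-mean smoothing windows) are not published; the defaults of
    0.5 s and 1.0 s are this implementation's choice.  ``median_stride``
    controls the strided evaluation of the running median (1 = exact,
    0 = auto stride of order/16; the median only serves as a slow baseline).
    """

    threshold_k_sd: float = 2.0
    merge_gap_s: float = 10.0
    exclusion_gap_s: float = 20.0
    max_duration_s: float = 10.0
    flank_nrem_s: float = 20.0
    rescore_max_s: float = 11.0
    envelope_sd_window_s: float = 0.5
    envelope_mean_window_s: float = 1.0
    median_filter_order_samples: int = 10000
    median_stride: int = 0
    rem_follow_window_s: float = 4.0
    wake_min_duration_s: float = 20.0

    def __post_init__(self) -> None:
        for name in (
            "threshold_k_sd",
            "merge_gap_s",
            "exclusion_gap_s",
            "max_duration_s",
            "flank_nrem_s",
            "rescore_max_s",
            "envelope_sd_window_s",
            "envelope_mean_window_s",
            "median_filter_order_samples",
            "rem_follow_window_s",
            "wake_min_duration_s",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.merge_gap_s > self.exclusion_gap_s:
            raise ValueError("merge_gap_s must not exceed exclusion_gap_s")


@dataclass
class Envelope:
    """Rectified EMG tonus series, aligned sample-for-sample with its source.

    ``threshold`` is filled in by peak detection (k x SD over NREM samples,
    or a manual override).
    """

    samples: np.ndarray
    sampling_rate: float
    threshold: float = float("nan")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sampling_rate

    def as_trace(self, label: str = "EMG envelope") -> SignalTrace:
        return SignalTrace(self.samples, self.sampling_rate, label=label)


def _moving_sd(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving standard deviation (reflect-padded edges)."""
    window = max(int(window), 2)
    m = uniform_filter1d(x, window, mode="reflect")
    m2 = uniform_filter1d(x * x, window, mode="reflect")
    var = np.maximum(m2 - m * m, 0.0)
    return np.sqrt(var)


def _running_median(x: np.ndarray, order: int, stride: int) -> np.ndarray:
    """Centered running median of window ``order``, evaluated every
    ``stride`` samples and linearly interpolated in between.

    ``stride=1`` is the exact sliding median.  The median tracks a slow
    (tens of seconds) baseline, so strided evaluation loses nothing at the
    event timescale while being orders of magnitude faster.
    """
    n = x.size
    if n < order:
        raise ValueError("trace too short for median filter order")
    if stride <= 0:
        stride = max(order // 16, 1)
    half = order // 2
    centers = np.arange(half, n - (order - half) + 1, stride)
    if centers.size == 0 or centers[-1] != n - (order - half):
        centers = np.append(centers, n - (order - half))
    starts = centers - half
    if stride == 1:
        from numpy.lib.stride_tricks import sliding_window_view

        med = np.median(sliding_window_view(x, order), axis=1)
        centers_full = np.arange(half, half + med.size)
        return np.interp(np.arange(n), centers_full, med)
    windows = np.empty((centers.size, order))
    for i, s in enumerate(starts):
        windows[i] = x[s : s + order]
    med = np.median(windows, axis=1)
    return np.interp(np.arange(n), centers, med)


def rectify_emg(emg: SignalTrace, cfg: DetectionConfig = DetectionConfig()) -> Envelope:
    """Filter and rectify the EMG into a non-negative tonus envelope.

    The raw EMG is rectified by a moving standard deviation (window
    ``envelope_sd_window_s``; offset-invariant, so electrode DC bias cancels),
    smoothed by a moving mean (window ``envelope_mean_window_s``), and a
    slow baseline estimated by a running median of order
    ``median_filter_order_samples`` is subtracted and the result floored at
    zero.  The output is aligned sample-for-sample with the input.
    """
    if emg.sampling_rate <= 0:
        raise ValueError("sampling rate must be positive")
    fs = emg.sampling_rate
    if emg.n_samples < cfg.median_filter_order_samples:
        raise ValueError("trace too short")
    sd_win = int(round(cfg.envelope_sd_window_s * fs))
    mean_win = max(int(round(cfg.envelope_mean_window_s * fs)), 1)
    env = _moving_sd(emg.samples, sd_win)
    env = uniform_filter1d(env, mean_win, mode="reflect")
    baseline = _running_median(env, cfg.median_filter_order_samples, cfg.median_stride)
    env = np.maximum(env - baseline, 0.0)
    return Envelope(env, fs)


def nrem_envelope_threshold(
    env: Envelope, hyp: Hypnogram, k_sd: float
) -> float:
    """k x the SD of the envelope over NREM samples (the sleeping muscle
    tone), the detector's amplitude criterion."""
    mask = hyp.sample_mask(NREM, env.sampling_rate, env.samples.size)
    if not mask.any():
        raise ValueError("no NREM available for threshold")
    return k_sd * float(np.std(env.samples[mask]))


def detect_emg_peaks(
    env: Envelope,
    hyp: Hypnogram,
    cfg: DetectionConfig = DetectionConfig(),
    threshold_override: Optional[float] = None,
) -> list:
    """Maximal supra-threshold runs of the envelope, as intervals.

    The threshold is ``threshold_k_sd`` x the envelope SD over NREM samples
    of ``hyp`` (pass the rescored hypnogram), or ``threshold_override`` when
    given.  Onset is the first sample above threshold, offset the first
    sample back below.  A constant envelope (SD = 0) yields no peaks.
    """
    if threshold_override is not None:
        thr = float(threshold_override)
    else:
        thr = nrem_envelope_threshold(env, hyp, cfg.threshold_k_sd)
    env.threshold = thr
    if thr <= 0:
        return []
    above = env.samples > thr
    if not above.any():
        return []
    d = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    stops = np.flatnonzero(d == -1) + 1
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        stops = np.r_[stops, above.size]
    fs = env.sampling_rate
    return [Interval(s / fs, (e - s) / fs) for s, e in zip(starts, stops)]


def _nrem_flank_ok(hyp: Hypnogram, t0: float, t1: float, flank_s: float) -> bool:
    """True when [t0 - flank, t0) and [t1, t1 + flank) are entirely NREM."""
    for lo, hi in ((t0 - flank_s, t0), (t1, t1 + flank_s)):
        if lo < hyp.start_time or hi > hyp.end_time:
            return False
        i0 = int(np.floor((lo - hyp.start_time) / hyp.epoch_s))
        i1 = int(np.ceil((hi - hyp.start_time) / hyp.epoch_s))
        i1 = min(i1, hyp.n_epochs)
        if not np.all(hyp.labels[i0:i1] == NREM):
            return False
    return True


def _rem_end_times(hyp: Hypnogram) -> np.ndarray:
    return np.array([iv.offset for iv in state_episodes(hyp, REM)])


def postprocess_events(
    candidates: Sequence[Interval],
    hyp: Hypnogram,
    cfg: DetectionConfig = DetectionConfig(),
    envelope: Optional[Envelope] = None,
) -> EventSet:
    """Apply the inclusion/exclusion rules to supra-threshold peaks.

    ``hyp`` must already be rescored.  Rules, in order:

    1. drop candidates whose midpoint lies outside NREM;
    2. combine candidates whose silent gap is < ``merge_gap_s`` (10 s);
    3. omit events whose gap to a neighbouring surviving event is
       < ``exclusion_gap_s`` (20 s) — *both* members are dropped, since
       neither is surrounded by undisturbed NREM;
    4. exclude events with duration > ``max_duration_s`` (10 s);
    5. exclude events whose onset falls within ``rem_follow_window_s``
       (4 s) after a REM episode's end;
    6. require >= ``flank_nrem_s`` (20 s) of uninterrupted NREM
       immediately before the onset and after the offset.

    Returns the surviving events as ``nrem_ma`` events; ``peak_amplitude``
    is filled from ``envelope`` when provided.
    """
    cand = list(candidates)
    for a, b in zip(cand, cand[1:]):
        if b.onset < a.onset:
            raise ValueError("candidate intervals must be sorted by onset")

    # 1. NREM gate on the midpoint
    kept = []
    for iv in cand:
        t = iv.midpoint
        if hyp.start_time <= t < hyp.end_time and hyp.state_at(t) == NREM:
            kept.append(iv)

    # 2. merge close peaks into one event
    merged = merge_intervals(kept, cfg.merge_gap_s)

    # 3. mutual-exclusion rule: simultaneous marking over the merged list
    drop = [False] * len(merged)
    for i in range(len(merged) - 1):
        gap = merged[i + 1].onset - merged[i].offset
        if gap < cfg.exclusion_gap_s:
            drop[i] = drop[i + 1] = True
    merged = [iv for iv, d in zip(merged, drop) if not d]

    # 4. duration cap
    merged = [iv for iv in merged if iv.duration <= cfg.max_duration_s]

    # 5. REM-follow exclusion
    rem_ends = _rem_end_times(hyp)
    if rem_ends.size:
        merged = [
            iv
            for iv in merged
            if not np.any((rem_ends <= iv.onset) & (iv.onset < rem_ends + cfg.rem_follow_window_s))
        ]

    # 6. undisturbed-NREM flanks
    merged = [iv for iv in merged if _nrem_flank_ok(hyp, iv.onset, iv.offset, cfg.flank_nrem_s)]

    return EventSet([_make_event(iv, NREM_MA, envelope) for iv in merged])


def _make_event(iv: Interval, kind: str, envelope: Optional[Envelope]) -> Event:
    peak = float("nan")
    if envelope is not None:
        fs = envelope.sampling_rate
        i0 = max(int(round(iv.onset * fs)), 0)
        i1 = min(int(round(iv.offset * fs)), envelope.samples.size)
        if i1 > i0:
            peak = float(np.max(envelope.samples[i0:i1]))
    return Event(iv.onset, iv.duration, kind=kind, peak_amplitude=peak)


def detect_microarousals(
    emg: SignalTrace,
    hyp: Hypnogram,
    cfg: DetectionConfig = DetectionConfig(),
) -> EventSet:
    """Full NREM micro-arousal detection pipeline (deterministic).

    Composition of intrusion rescoring, EMG rectification, supra-threshold
    peak detection and the rule-based post-processing.  Returns ``nrem_ma``
    events sorted by onset.
    """
    hyp_r = rescore_short_intrusions(hyp, cfg.rescore_max_s)
    env = rectify_emg(emg, cfg)
    peaks = detect_emg_peaks(env, hyp_r, cfg)
    return postprocess_events(peaks, hyp_r, cfg, envelope=env)


def detect_rem_terminating_mas(
    emg: SignalTrace,
    hyp: Hypnogram,
    cfg: DetectionConfig = DetectionConfig(),
    threshold_override: Optional[float] = None,
) -> EventSet:
    """Micro-arousals that terminate REM sleep.

    Same envelope/peak machinery, but only merged peaks whose onset falls
    within ``rem_follow_window_s`` (4 s) after a REM episode's end are kept.
    ``threshold_override`` replaces the 2x-SD threshold (EMG after REM is
    variable across animals, so per-recording thresholds may be tuned).
    An all-NREM recording simply yields an empty set.
    """
    hyp_r = rescore_short_intrusions(hyp, cfg.rescore_max_s)
    rem_ends = _rem_end_times(hyp_r)
    if rem_ends.size == 0:
        return EventSet([])
    env = rectify_emg(emg, cfg)
    peaks = detect_emg_peaks(env, hyp_r, cfg, threshold_override=threshold_override)
    merged = merge_intervals(peaks, cfg.merge_gap_s)
    out = [
        iv
        for iv in merged
        if np.any((rem_ends <= iv.onset) & (iv.onset < rem_ends + cfg.rem_follow_window_s))
    ]
    return EventSet([_make_event(iv, REM_MA, env) for iv in out])


def detect_wake_transitions(
    emg: SignalTrace,
    hyp: Hypnogram,
    cfg: DetectionConfig = DetectionConfig(),
) -> EventSet:
    """Sleep-to-wake transitions: muscle-activity bouts longer than
    ``wake_min_duration_s`` (20 s) that begin in NREM sleep.

    The 10-s duration cap and the exclusion rules do not apply; the bout is
    an awakening, not a micro-arousal.
    """
    hyp_r = rescore_short_intrusions(hyp, cfg.rescore_max_s)
    env = rectify_emg(emg, cfg)
    peaks = detect_emg_peaks(env, hyp_r, cfg)
    merged = merge_intervals(peaks, cfg.merge_gap_s)
    out = []
    for iv in merged:
        if iv.duration <= cfg.wake_min_duration_s:
            continue
        if not (hyp_r.start_time <= iv.onset < hyp_r.end_time):
            continue
        if hyp_r.state_at(iv.onset) == NREM:
            out.append(iv)
    return EventSet([_make_event(iv, WAKE_TRANSITION, env) for iv in out])


def average_rectified_emg(
    env: Envelope,
    events: EventSet,
    pre_s: float = 10.0,
    post_s: float = 10.0,
):
    """Event-locked mean (and SEM) of the rectified EMG envelope.

    Returns ``(times, mean, sem)`` where ``times`` is relative to event
    onset.  All event windows must lie inside the recording.
    """
    if len(events) == 0:
        raise ValueError("no events")
    fs = env.sampling_rate
    n_pre = int(round(pre_s * fs))
    n_post = int(round(post_s * fs))
    n = n_pre + n_post
    segs = np.empty((len(events), n))
    for k, ev in enumerate(events):
        i0 = int(round(ev.onset * fs)) - n_pre
        i1 = i0 + n
        if i0 < 0 or i1 > env.samples.size:
            raise ValueError(f"event at {ev.onset:.1f} s lacks {pre_s}/{post_s} s context")
        segs[k] = env.samples[i0:i1]
    times = (np.arange(n) - n_pre) / fs
    mean = segs.mean(axis=0)
    if len(events) > 1:
        sem = segs.std(axis=0, ddof=1) / np.sqrt(len(events))
    else:
        sem = np.zeros(n)
    return times, mean, sem
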