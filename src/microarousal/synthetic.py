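"""Synthetic polysomnography with known ground truth.

Generates complete recordings — a semi-Markov hypnogram at 4-s epoch
resolution, a nuchal-EMG trace with brief muscle bursts planted during NREM
sleep, a motor-cortex-like LFP whose 1-4 Hz (SWA) envelope follows vigilance
state and a two-state homeostatic (process-S analogue) gain, and 16-channel
multi-unit spike trains whose rates are modulated around the planted
arousals.  Every planted quantity is recorded in a GroundTruth object so
detection and parameter-recovery can be scored exactly.

What the generator emulates: state-dependent EMG tone (wake >> NREM > REM),
micro-arousal bursts at a Poisson rate within NREM with durations mostly
2-4 s and a tail to ~12 s, SWA that is strongest in NREM and rises with
time-awake, a pre-arousal SWA rise, a broadband power drop during the
arousal, a post-arousal SWA level set by a planted linear law in the prior
6-h NREM fraction, and channels whose firing surges just before onset or is
suppressed just after.  What it does not emulate: real spindle/theta
microstructure, volume conduction, infraslow (~0.02 Hz) arousal timing
(arousal times are Poisson by default), or scorer noise in the hypnogram.

A single integer seed is split into independent per-signal streams
(``numpy`` SeedSequence spawning), so adding a signal never perturbs the
others; identical config + seed gives bit-identical output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import signal as sps

from .core import Event, EventSet, Interval, NREM_MA, SignalTrace, merge_intervals
from .firing import SpikeTrains
from .hypnogram import Hypnogram, NREM, REM, WAKE, rescore_short_intrusions, state_episodes
from .ma_detect import DetectionConfig

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "PlantedBurst",
    "generate_hypnogram",
    "generate_emg",
    "generate_lfp",
    "generate_spikes",
    "generate_recording",
    "simulate_history_points",
    "RecordingBundle",
]


@dataclass(frozen=True)
class PlantedBurst:
    """One true muscle-activity event with its rule-compliance bookkeeping.

    ``source`` is ``"burst"`` for bursts planted by the EMG generator and
    ``"wake_intrusion"`` for brief scored-wake periods inside NREM, whose
    wake-level muscle tone the intrusion-rescoring step deliberately folds
    back into NREM so the detector can pick them up.  ``group`` indexes the
    merged event the entry belongs to after the 10-s combination rule;
    ``satisfies_rules`` marks whether that merged event survives all
    inclusion criteria (and hence should be reported by the detector as a
    NREM micro-arousal).
    """

    onset: float
    duration: float
    group: int = -1
    satisfies_rules: bool = False
    source: str = "burst"


@dataclass(frozen=True)
class SyntheticConfig:
    """All generator knobs with study-realistic defaults.

    Stage dwell times are lognormal (median seconds, log-sigma); the
    transition matrix sends wake to NREM always, NREM mostly back to wake
    with occasional REM, and REM to either.  ``ma_rate_per_min_nrem`` is the
    Poisson planting rate of EMG bursts inside NREM episodes;
    ``emg_burst_snr`` scales burst amplitude in NREM-baseline SDs; burst
    durations are lognormal truncated to [0.5, 12] s.  The homeostatic gain
    (process-S analogue) rises during wake with an 8-h time constant and
    decays during NREM with a 2-h constant.  The planted post-arousal SWA
    law is ``post_swa_intercept + post_swa_slope * (% NREM in prior 6 h)``
    percent of baseline SWA.
    """

    seed: int = 0
    duration_s: float = 7200.0
    epoch_s: float = 4.0
    sampling_rate: float = 256.0
    lights_on: float = 0.0
    sd_block: Optional[tuple] = None  # (start_s, end_s) enforced wake

    # hypnogram: lognormal dwell (median_s, sigma_log) per state
    dwell_median_s: dict = field(
        default_factory=lambda: {"W": 40.0, "N": 120.0, "R": 60.0}
    )
    dwell_sigma_log: dict = field(
        default_factory=lambda: {"W": 1.0, "N": 0.8, "R": 0.5}
    )
    # transition probabilities from each state (to the other two)
    transitions: dict = field(
        default_factory=lambda: {
            "W": {"N": 1.0, "R": 0.0},
            "N": {"W": 0.8, "R": 0.2},
            "R": {"W": 0.5, "N": 0.5},
        }
    )

    # EMG
    emg_tone_sd: dict = field(
        default_factory=lambda: {"W": 1.0, "N": 0.15, "R": 0.08}
    )
    # wake muscle tone is phasic: lognormal amplitude modulation with a
    # short correlation time (movement bouts), not a stationary hum
    wake_tone_mod_sigma_log: float = 0.6
    wake_tone_mod_tau_s: float = 2.0
    ma_rate_per_min_nrem: float = 0.8
    emg_burst_snr: float = 6.0
    burst_duration_median_s: float = 3.0
    burst_duration_sigma_log: float = 0.6
    burst_duration_range_s: tuple = (0.5, 12.0)
    burst_ramp_s: float = 0.05

    # LFP
    lfp_1f_exponent: float = 1.5
    lfp_background_scale: float = 0.3
    swa_gain_by_state: dict = field(
        default_factory=lambda: {"W": 0.3, "N": 1.0, "R": 0.2}
    )
    s_initial: float = 0.6
    s_rise_tau_s: float = 28800.0
    s_decay_tau_s: float = 7200.0
    s_floor: float = 0.2
    pre_rise_frac: float = 0.3
    pre_rise_window_s: float = 10.0
    during_drop_frac: float = 0.6
    post_swa_intercept: float = 250.0
    post_swa_slope: float = -2.0
    post_window: tuple = (3.0, 8.0)
    history_lookback_s: float = 21600.0

    # spikes
    n_channels: int = 16
    base_rate_hz: dict = field(
        default_factory=lambda: {"W": 10.0, "N": 6.0, "R": 7.0}
    )
    # per-channel profiles: (kind, amplitude); kind in {surge, suppress, flat}
    channel_effect_profiles: tuple = (
        ("surge", 1.5),
        ("surge", 1.5),
        ("surge", 1.5),
        ("surge", 1.5),
        ("suppress", 0.7),
        ("suppress", 0.7),
        ("suppress", 0.7),
        ("suppress", 0.7),
        ("suppress", 0.7),
        ("suppress", 0.7),
        ("flat", 0.0),
        ("flat", 0.0),
        ("flat", 0.0),
        ("flat", 0.0),
        ("flat", 0.0),
        ("flat", 0.0),
    )
    surge_peak_s: float = -0.7
    surge_width_s: float = 0.4
    suppress_span_s: float = 3.0

    def replace(self, **kw) -> "SyntheticConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class GroundTruth:
    """Everything planted: bursts with rule flags, per-channel effect labels,
    and the planted SWA-history law."""

    bursts: list = field(default_factory=list)
    channel_labels: list = field(default_factory=list)
    post_swa_intercept: float = float("nan")
    post_swa_slope: float = float("nan")

    def expected_events(self) -> EventSet:
        """Merged spans of rule-satisfying planted bursts — what the
        detector is expected to report."""
        groups: dict = {}
        for b in self.bursts:
            if b.satisfies_rules:
                iv = groups.get(b.group)
                lo = b.onset if iv is None else min(iv[0], b.onset)
                hi = b.onset + b.duration if iv is None else max(iv[1], b.onset + b.duration)
                groups[b.group] = (lo, hi)
        evs = [Event(lo, hi - lo, kind=NREM_MA) for lo, hi in sorted(groups.values())]
        return EventSet(evs)


def _streams(seed: int):
    """Independent per-signal random streams from one integer seed."""
    ss = np.random.SeedSequence(seed)
    names = ("hypnogram", "emg", "lfp", "spikes", "misc")
    children = ss.spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


# ---------------------------------------------------------------------------
# hypnogram
# ---------------------------------------------------------------------------


def generate_hypnogram(cfg: SyntheticConfig, rng: Optional[np.random.Generator] = None) -> Hypnogram:
    """Semi-Markov vigilance-state sequence quantized to the epoch grid.

    Dwell times are lognormal per state; transitions follow the configured
    matrix.  An optional enforced-wake block (``sd_block``) emulates sleep
    deprivation by novel objects.  Deterministic for a fixed config + seed.
    """
    if cfg.duration_s < 600:
        raise ValueError("duration must be at least 10 min")
    for st in ("W", "N", "R"):
        if cfg.dwell_median_s[st] <= 0:
            raise ValueError("dwell medians must be positive")
        probs = cfg.transitions[st]
        total = sum(probs.values())
        if any(p < 0 for p in probs.values()) or (total > 0 and abs(total - 1.0) > 1e-9):
            # a zero row is allowed: the state is absorbing
            raise ValueError(f"invalid transition distribution from {st}")
    if rng is None:
        rng = _streams(cfg.seed)["hypnogram"]
    n_epochs = int(np.ceil(cfg.duration_s / cfg.epoch_s))
    labels = []
    state = WAKE
    while len(labels) < n_epochs:
        med = cfg.dwell_median_s[state]
        sig = cfg.dwell_sigma_log[state]
        dwell = med * np.exp(sig * rng.standard_normal())
        k = max(int(round(dwell / cfg.epoch_s)), 1)
        labels.extend([state] * k)
        targets, probs = zip(*cfg.transitions[state].items())
        if sum(probs) == 0:  # absorbing state
            labels.extend([state] * (n_epochs - len(labels)))
            break
        state = rng.choice(targets, p=np.asarray(probs) / sum(probs))
    arr = np.array(labels[:n_epochs])
    if cfg.sd_block is not None:
        t0, t1 = cfg.sd_block
        i0 = max(int(np.floor(t0 / cfg.epoch_s)), 0)
        i1 = min(int(np.ceil(t1 / cfg.epoch_s)), n_epochs)
        arr[i0:i1] = WAKE
    return Hypnogram(arr, epoch_s=cfg.epoch_s)


# ---------------------------------------------------------------------------
# EMG
# ---------------------------------------------------------------------------


def _burst_envelope(n: int, ramp: int) -> np.ndarray:
    """Unit-amplitude burst envelope with raised-cosine on/off ramps."""
    env = np.ones(n)
    r = min(ramp, n // 2)
    if r > 0:
        t = np.linspace(0, np.pi, r)
        env[:r] = 0.5 * (1 - np.cos(t))
        env[-r:] = 0.5 * (1 + np.cos(t))
    return env


def _plant_bursts(hyp: Hypnogram, cfg: SyntheticConfig, rng: np.random.Generator) -> list:
    """Draw Poisson burst times within NREM episodes."""
    rate_hz = cfg.ma_rate_per_min_nrem / 60.0
    lo, hi = cfg.burst_duration_range_s
    bursts = []
    for ep in state_episodes(hyp, NREM):
        n = rng.poisson(rate_hz * ep.duration)
        if n == 0:
            continue
        onsets = np.sort(rng.uniform(ep.onset, ep.offset, size=n))
        for t in onsets:
            d = cfg.burst_duration_median_s * np.exp(
                cfg.burst_duration_sigma_log * rng.standard_normal()
            )
            d = float(np.clip(d, lo, hi))
            d = min(d, ep.offset - t)  # keep the burst inside its episode
            if d >= lo:
                bursts.append((float(t), d))
    bursts.sort()
    return bursts


def _wake_intrusion_events(hyp: Hypnogram, det: DetectionConfig) -> list:
    """Wake sub-runs of rescored short intrusions inside NREM.

    These carry wake-level muscle tone and therefore constitute true
    EMG events after the rescoring step (the manually scored
    micro-arousals that rescoring exists to recover).  REM portions of a
    mixed intrusion have atonic EMG and generate no event.
    """
    labels = hyp.labels
    n = labels.size
    out = []
    start = 0
    non_nrem = labels != NREM
    for i in range(1, n + 1):
        if i == n or non_nrem[i] != non_nrem[start]:
            if non_nrem[start]:
                dur = (i - start) * hyp.epoch_s
                interior = start > 0 and i < n
                if interior and dur < det.rescore_max_s:
                    # wake sub-runs inside this rescored intrusion
                    j = start
                    while j < i:
                        if labels[j] == WAKE:
                            j2 = j
                            while j2 < i and labels[j2] == WAKE:
                                j2 += 1
                            out.append(
                                (
                                    hyp.start_time + j * hyp.epoch_s,
                                    (j2 - j) * hyp.epoch_s,
                                )
                            )
                            j = j2
                        else:
                            j += 1
            start = i
    return out


def _flag_bursts(
    bursts: Sequence[tuple],
    hyp: Hypnogram,
    det: DetectionConfig,
) -> list:
    """Apply the printed inclusion rules to the true-event list.

    Independent, geometry-only re-statement of the rules (no envelope, no
    thresholding): merge events closer than the 10-s gap, then drop merged
    events that are > 10 s long, within 20 s of a neighbour, outside NREM at
    their midpoint, within 4 s after a REM end, or lacking 20-s NREM flanks.
    ``bursts`` entries are ``(onset, duration, source)``.
    """
    hyp_r = rescore_short_intrusions(hyp, det.rescore_max_s)
    rem_ends = [iv.offset for iv in state_episodes(hyp_r, REM)]
    nrem_eps = state_episodes(hyp_r, NREM)

    # group events by the merge rule
    groups: list = []
    for k, (t, d, _src) in enumerate(bursts):
        if groups and t - groups[-1]["hi"] < det.merge_gap_s:
            g = groups[-1]
            g["hi"] = max(g["hi"], t + d)
            g["members"].append(k)
        else:
            groups.append({"lo": t, "hi": t + d, "members": [k]})

    # neighbour-gap exclusion (simultaneous marking)
    keep = [True] * len(groups)
    for i in range(len(groups) - 1):
        if groups[i + 1]["lo"] - groups[i]["hi"] < det.exclusion_gap_s:
            keep[i] = keep[i + 1] = False

    def _in_nrem(t: float) -> bool:
        return any(ep.onset <= t < ep.offset for ep in nrem_eps)

    def _flanks_ok(lo: float, hi: float) -> bool:
        for a, b in ((lo - det.flank_nrem_s, lo), (hi, hi + det.flank_nrem_s)):
            if a < hyp_r.start_time or b > hyp_r.end_time:
                return False
            if not any(ep.onset <= a and b <= ep.offset for ep in nrem_eps):
                return False
        return True

    out = []
    for gi, (g, k0) in enumerate(zip(groups, keep)):
        lo, hi = g["lo"], g["hi"]
        ok = (
            k0
            and (hi - lo) <= det.max_duration_s
            and _in_nrem((lo + hi) / 2.0)
            and not any(e <= lo < e + det.rem_follow_window_s for e in rem_ends)
            and _flanks_ok(lo, hi)
        )
        for k in g["members"]:
            t, d, src = bursts[k]
            out.append(
                PlantedBurst(onset=t, duration=d, group=gi, satisfies_rules=ok, source=src)
            )
    return out


def generate_emg(
    hyp: Hypnogram,
    cfg: SyntheticConfig,
    rng: Optional[np.random.Generator] = None,
) -> tuple:
    """Synthetic nuchal EMG: state-toned Gaussian noise plus planted bursts.

    Baseline noise SD follows the vigilance state (wake >> NREM > REM).
    Bursts are extra Gaussian noise with a raised-cosine amplitude envelope
    of ``emg_burst_snr`` x the NREM baseline SD, planted at Poisson times
    inside NREM.  Returns ``(SignalTrace, GroundTruth)``; the truth flags
    each burst for whether its merged event satisfies the inclusion rules.
    """
    if rng is None:
        rng = _streams(cfg.seed)["emg"]
    fs = cfg.sampling_rate
    n = int(round(hyp.duration_s * fs))
    sd = np.empty(n)
    for st, tone in cfg.emg_tone_sd.items():
        mask = hyp.sample_mask(st, fs, n)
        sd[mask] = tone
    if cfg.wake_tone_mod_sigma_log > 0:
        # phasic wake tone: smoothed lognormal modulation (movements), so
        # sustained wakefulness shows recurring EMG peaks rather than a
        # stationary hum
        from scipy.ndimage import gaussian_filter1d

        g = rng.standard_normal(n)
        tau = cfg.wake_tone_mod_tau_s * fs
        g = gaussian_filter1d(g, tau, mode="reflect")
        gs = g.std()
        if gs > 0:
            g /= gs
        s = cfg.wake_tone_mod_sigma_log
        mod = np.exp(s * g - s * s / 2.0)
        wmask = hyp.sample_mask(WAKE, fs, n)
        sd[wmask] *= mod[wmask]
    x = rng.standard_normal(n) * sd

    bursts = _plant_bursts(hyp, cfg, rng)
    amp = cfg.emg_burst_snr * cfg.emg_tone_sd[NREM]
    ramp = int(round(cfg.burst_ramp_s * fs))
    for t, d in bursts:
        i0 = int(round(t * fs))
        i1 = min(int(round((t + d) * fs)), n)
        if i1 <= i0:
            continue
        env = _burst_envelope(i1 - i0, ramp)
        x[i0:i1] += rng.standard_normal(i1 - i0) * amp * env

    det = DetectionConfig()
    all_events = sorted(
        [(t, d, "burst") for t, d in bursts]
        + [(t, d, "wake_intrusion") for t, d in _wake_intrusion_events(hyp, det)]
    )
    truth = GroundTruth(
        bursts=_flag_bursts(all_events, hyp, det),
        post_swa_intercept=cfg.post_swa_intercept,
        post_swa_slope=cfg.post_swa_slope,
    )
    return SignalTrace(x, fs, label="EMG", unit="a.u."), truth


# ---------------------------------------------------------------------------
# LFP
# ---------------------------------------------------------------------------


def _one_over_f_noise(n: int, exponent: float, rng: np.random.Generator) -> np.ndarray:
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0)
    f[0] = f[1] if n > 1 else 1.0
    spec *= f ** (-exponent / 2.0)
    x = np.fft.irfft(spec, n)
    s = x.std()
    return x / s if s > 0 else x


def _homeostatic_gain(hyp: Hypnogram, cfg: SyntheticConfig) -> np.ndarray:
    """Per-epoch process-S analogue: rises in wake, decays in NREM."""
    s = np.empty(hyp.n_epochs)
    val = cfg.s_initial
    dt = hyp.epoch_s
    for i, lab in enumerate(hyp.labels):
        if lab == WAKE:
            val += (1.0 - val) * dt / cfg.s_rise_tau_s
        elif lab == NREM:
            val += (cfg.s_floor - val) * dt / cfg.s_decay_tau_s
        s[i] = val
    return s


def _prior_nrem_fraction(hyp: Hypnogram, t: float, lookback: float) -> float:
    lo = max(t - lookback, hyp.start_time)
    if t - lo <= 0:
        return 0.0
    from .hypnogram import fraction_in_state

    return fraction_in_state(hyp, Interval(lo, t - lo), NREM)


def generate_lfp(
    hyp: Hypnogram,
    cfg: SyntheticConfig,
    truth: Optional[GroundTruth] = None,
    rng: Optional[np.random.Generator] = None,
) -> SignalTrace:
    """Synthetic LFP: 1/f^alpha background plus a 1-4 Hz oscillation whose
    envelope follows state, homeostatic gain, and the planted peri-event
    program.

    Around every planted burst: the SWA envelope ramps up by
    ``pre_rise_frac`` over the 10 s before onset, the whole signal is
    attenuated by ``sqrt(1 - during_drop_frac)`` during the burst (a
    broadband power drop), and inside the post window (3-8 s after onset)
    the SWA amplitude is pinned to the planted linear law in the prior 6-h
    NREM fraction — the law that the history regression should recover.
    """
    if rng is None:
        rng = _streams(cfg.seed)["lfp"]
    fs = cfg.sampling_rate
    n = int(round(hyp.duration_s * fs))

    # narrowband 1-4 Hz carrier with unit SD
    carrier = rng.standard_normal(n)
    sos = sps.butter(4, [1.0, 4.0], btype="bandpass", fs=fs, output="sos")
    carrier = sps.sosfiltfilt(sos, carrier)
    cs = carrier.std()
    if cs > 0:
        carrier /= cs

    # amplitude program: state gain x sqrt(homeostatic gain)
    gain_epoch = np.array([cfg.swa_gain_by_state[lab] for lab in hyp.labels])
    s_epoch = _homeostatic_gain(hyp, cfg)
    amp_epoch = gain_epoch * np.sqrt(s_epoch)
    idx = np.minimum((np.arange(n) / fs / hyp.epoch_s).astype(int), hyp.n_epochs - 1)
    amp = amp_epoch[idx]

    # the NREM amplitude at the initial homeostatic level defines "baseline"
    baseline_amp = cfg.swa_gain_by_state[NREM] * np.sqrt(cfg.s_initial)

    broadband = np.ones(n)
    if truth is not None:
        t_axis = np.arange(n) / fs
        for b in truth.bursts:
            i_on = int(round(b.onset * fs))
            # pre-onset SWA rise (half-cosine ramp)
            i_pre = max(i_on - int(round(cfg.pre_rise_window_s * fs)), 0)
            if i_on > i_pre:
                ramp = 0.5 * (1 - np.cos(np.pi * np.linspace(0, 1, i_on - i_pre)))
                amp[i_pre:i_on] *= 1.0 + cfg.pre_rise_frac * ramp
            # during-event broadband suppression
            i_off = min(int(round((b.onset + b.duration) * fs)), n)
            if i_off > i_on:
                broadband[i_on:i_off] = np.sqrt(max(1.0 - cfg.during_drop_frac, 0.0))
            # post window: pin SWA amplitude to the planted history law;
            # the rebound starts once the arousal itself (broadband
            # suppression) has ended
            frac = _prior_nrem_fraction(hyp, b.onset, cfg.history_lookback_s)
            target_pct = cfg.post_swa_intercept + cfg.post_swa_slope * frac * 100.0
            target_pct = max(target_pct, 5.0)
            post_start = max(b.onset + cfg.post_window[0], b.onset + b.duration)
            p0 = int(round(post_start * fs))
            p1 = min(int(round((b.onset + cfg.post_window[1]) * fs)), n)
            if p1 > p0:
                amp[p0:p1] = baseline_amp * np.sqrt(target_pct / 100.0)

    background = _one_over_f_noise(n, cfg.lfp_1f_exponent, rng) * cfg.lfp_background_scale
    x = (carrier * amp + background) * broadband
    return SignalTrace(x, fs, label="LFP", unit="a.u.")


# ---------------------------------------------------------------------------
# spikes
# ---------------------------------------------------------------------------


def generate_spikes(
    hyp: Hypnogram,
    cfg: SyntheticConfig,
    truth: Optional[GroundTruth] = None,
    rng: Optional[np.random.Generator] = None,
) -> SpikeTrains:
    """Inhomogeneous-Poisson multi-unit trains per channel.

    The base rate follows the vigilance state; around every planted burst
    the rate is multiplied by the channel's effect profile: a Gaussian surge
    peaking ``surge_peak_s`` before onset, a half-cosine suppression over
    the first ``suppress_span_s`` after onset, or flat.  Spike times are
    drawn on a 10-ms grid (Poisson counts, uniform placement within bins).
    """
    if rng is None:
        rng = _streams(cfg.seed)["spikes"]
    fs_grid = 100.0  # 10-ms rate grid
    n = int(round(hyp.duration_s * fs_grid))
    t_grid = (np.arange(n) + 0.5) / fs_grid

    base = np.empty(n)
    for st, r in cfg.base_rate_hz.items():
        mask = hyp.sample_mask(st, fs_grid, n)
        base[mask] = r

    onsets = np.array([b.onset for b in truth.bursts]) if truth is not None else np.array([])
    durs = np.array([b.duration for b in truth.bursts]) if truth is not None else np.array([])

    profiles = list(cfg.channel_effect_profiles)[: cfg.n_channels]
    while len(profiles) < cfg.n_channels:
        profiles.append(("flat", 0.0))

    trains = []
    labels = []
    for kind, ampl in profiles:
        mult = np.ones(n)
        if onsets.size and kind != "flat":
            for t0, d in zip(onsets, durs):
                if kind == "surge":
                    lo = t0 + cfg.surge_peak_s - 4 * cfg.surge_width_s
                    hi = t0 + cfg.surge_peak_s + 4 * cfg.surge_width_s
                    i0 = max(int(lo * fs_grid), 0)
                    i1 = min(int(hi * fs_grid), n)
                    if i1 > i0:
                        tt = t_grid[i0:i1] - (t0 + cfg.surge_peak_s)
                        mult[i0:i1] *= 1.0 + ampl * np.exp(
                            -(tt**2) / (2 * cfg.surge_width_s**2)
                        )
                elif kind == "suppress":
                    i0 = max(int(t0 * fs_grid), 0)
                    i1 = min(int((t0 + cfg.suppress_span_s) * fs_grid), n)
                    if i1 > i0:
                        ph = np.linspace(0, np.pi, i1 - i0)
                        mult[i0:i1] *= 1.0 - ampl * np.sin(ph)
        rate = np.clip(base * mult, 0.0, None)
        counts = rng.poisson(rate / fs_grid)
        spikes = []
        nz = np.flatnonzero(counts)
        for i in nz:
            spikes.append((i + rng.random(counts[i])) / fs_grid)
        times = np.sort(np.concatenate(spikes)) if spikes else np.empty(0)
        times = times[times < hyp.duration_s]
        trains.append(times)
        labels.append(kind)
    if truth is not None:
        truth.channel_labels = labels
    return SpikeTrains(trains=trains, duration_s=hyp.duration_s, channel_labels=labels)


# ---------------------------------------------------------------------------
# bundle
# ---------------------------------------------------------------------------


@dataclass
class RecordingBundle:
    """One synthetic recording: hypnogram, EMG, LFP, spike trains, truth,
    and the config that produced it."""

    hyp: Hypnogram
    emg: SignalTrace
    lfp: SignalTrace
    spikes: SpikeTrains
    truth: GroundTruth
    config: SyntheticConfig


def generate_recording(cfg: SyntheticConfig) -> RecordingBundle:
    """Generate a full recording from one seed (bit-reproducible)."""
    streams = _streams(cfg.seed)
    hyp = generate_hypnogram(cfg, streams["hypnogram"])
    emg, truth = generate_emg(hyp, cfg, streams["emg"])
    lfp = generate_lfp(hyp, cfg, truth, streams["lfp"])
    spikes = generate_spikes(hyp, cfg, truth, streams["spikes"])
    return RecordingBundle(hyp=hyp, emg=emg, lfp=lfp, spikes=spikes, truth=truth, config=cfg)


# ---------------------------------------------------------------------------
# points-level history simulator
# ---------------------------------------------------------------------------


def simulate_history_points(
    n: int,
    rng: np.random.Generator,
    post_slope: float = -2.0,
    post_intercept: float = 250.0,
    surround_slope: float = -1.0,
    surround_intercept: float = 160.0,
    noise_sd: float = 25.0,
    nrem_pct_range: tuple = (0.0, 60.0),
) -> list:
    """Draw HistoryPoints directly from the planted linear laws.

    Prior-NREM percentages are uniform on ``nrem_pct_range``; post and
    surround SWA are the respective lines plus independent Gaussian noise
    (SD ``noise_sd`` percent).  This is the statistical analogue of the
    signal-level generator, used for slope-recovery and power studies where
    thousands of regressions are needed.
    """
    from .homeostasis import HistoryPoint

    x = rng.uniform(*nrem_pct_range, size=n)
    post = post_intercept + post_slope * x + rng.standard_normal(n) * noise_sd
    surround = (
        surround_intercept + surround_slope * x + rng.standard_normal(n) * noise_sd
    )
    return [
        HistoryPoint(
            event_id=i,
            prior_nrem_fraction=float(x[i] / 100.0),
            post_swa_pct=float(post[i]),
            surround_swa_pct=float(surround[i]),
        )
        for i in range(n)
    ]
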