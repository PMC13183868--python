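"""LFP/EEG spectral analysis.

Conventions follow the analysis pipeline this package implements: signals at
256 Hz, a 20th-order Butterworth band-pass (1-30 Hz) applied zero-phase,
short-time spectrograms with 500-ms non-overlapping Hann windows, Welch PSDs
on a 0.5-Hz grid (Hann, zero overlap), and the standard rodent frequency
bands (SWA 1-4, theta 4-10, sigma 12-16, beta 16-30, gamma 30-80 Hz).

SWA (slow-wave activity, 1-4 Hz power) is the homeostatic sleep-pressure
marker; the peri-event operations express it as percent change from a
pre-event baseline window or as percent of a recording-level NREM baseline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from scipy import signal as sps

from .core import EventSet, Interval, SignalTrace
from .hypnogram import Hypnogram, NREM, state_episodes

__all__ = [
    "Spectrogram",
    "PSD",
    "BandDefinition",
    "BANDS",
    "SWA",
    "bandpass",
    "spectrogram",
    "welch_psd",
    "band_power",
    "peri_event_band_timecourse",
    "psd_before_during_after",
    "post_ma_swa",
    "nrem_swa_baseline",
]

log = logging.getLogger(__name__)


@dataclass
class Spectrogram:
    """Short-time power representation: ``power[time, frequency]`` with
    window-center ``times`` (s) and ``freqs`` (Hz)."""

    power: np.ndarray
    times: np.ndarray
    freqs: np.ndarray

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0]) if self.times.size > 1 else float("nan")


@dataclass
class PSD:
    """Welch power spectral density on a regular frequency grid."""

    freqs: np.ndarray
    density: np.ndarray

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])


@dataclass(frozen=True)
class BandDefinition:
    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0 <= self.lo < self.hi):
            raise ValueError("band must satisfy 0 <= lo < hi")


# Canonical bands. SWA deliberately starts at 1 Hz (not 0.5) so that
# movement-related low-frequency artefacts around arousals stay out.
SWA = BandDefinition("swa", 1.0, 4.0)
THETA = BandDefinition("theta", 4.0, 10.0)
SIGMA = BandDefinition("sigma", 12.0, 16.0)
BETA = BandDefinition("beta", 16.0, 30.0)
GAMMA = BandDefinition("gamma", 30.0, 80.0)
BANDS = {b.name: b for b in (SWA, THETA, SIGMA, BETA, GAMMA)}


def bandpass(
    trace: SignalTrace,
    lo: float = 1.0,
    hi: float = 30.0,
    order: int = 20,
) -> SignalTrace:
    """Zero-phase Butterworth band-pass.

    ``order`` is the overall filter order (a 20th-order band-pass is a
    10-section Butterworth design in scipy terms).  Realized as cascaded
    second-order sections for numerical stability and applied forward-
    backward so event-locked latencies are not shifted (the effective
    magnitude response is squared).
    """
    fs = trace.sampling_rate
    nyq = fs / 2.0
    if not (0 < lo < hi):
        raise ValueError("need 0 < lo < hi")
    if hi >= nyq:
        raise ValueError(f"high cutoff {hi} Hz >= Nyquist {nyq} Hz")
    if order % 2:
        raise ValueError("band-pass order must be even")
    sos = sps.butter(order // 2, [lo, hi], btype="bandpass", fs=fs, output="sos")
    y = sps.sosfiltfilt(sos, trace.samples)
    return SignalTrace(y, fs, label=trace.label, unit=trace.unit)


def bandpass_sos(lo: float, hi: float, order: int, fs: float) -> np.ndarray:
    """The SOS coefficients used by :func:`bandpass` (for response checks)."""
    return sps.butter(order // 2, [lo, hi], btype="bandpass", fs=fs, output="sos")


def spectrogram(
    trace: SignalTrace,
    window_s: float = 0.5,
    overlap: float = 0.0,
    taper: str = "hann",
) -> Spectrogram:
    """Short-time spectrogram with consecutive ``window_s`` windows.

    Zero overlap by default; time stamps are window centers.  The per-window
    estimate is a tapered periodogram (power spectral density scaling).
    """
    fs = trace.sampling_rate
    nperseg = int(round(window_s * fs))
    if nperseg > trace.n_samples:
        raise ValueError("window longer than trace")
    noverlap = int(round(overlap * nperseg))
    freqs, times, power = sps.spectrogram(
        trace.samples,
        fs=fs,
        window=taper,
        nperseg=nperseg,
        noverlap=noverlap,
        detrend=False,
        scaling="density",
        mode="psd",
    )
    return Spectrogram(power=power.T, times=times, freqs=freqs)


def welch_psd(trace: SignalTrace, resolution_hz: float = 0.5) -> PSD:
    """Welch PSD from Hann-tapered, non-overlapping segments.

    The segment length is ``sampling_rate / resolution_hz`` samples (512 at
    256 Hz), which puts the estimate on an exact ``resolution_hz`` grid.
    """
    fs = trace.sampling_rate
    nperseg = int(round(fs / resolution_hz))
    if trace.n_samples < nperseg:
        raise ValueError("trace shorter than one Welch segment")
    freqs, density = sps.welch(
        trace.samples,
        fs=fs,
        window="hann",
        nperseg=nperseg,
        noverlap=0,
        detrend=False,
        scaling="density",
    )
    return PSD(freqs=freqs, density=density)


def band_power(
    spec: Union[Spectrogram, PSD],
    band: BandDefinition,
    mode: str = "mean",
):
    """Band power from a spectrogram (per time bin) or a PSD (scalar).

    ``mode="mean"`` averages the power of the frequency bins with
    ``lo <= f <= hi`` (the spectrogram-averaging convention used for band
    time courses); ``mode="integral"`` integrates the density over the band
    (trapezoid), which for a sinusoid of amplitude A recovers A^2/2.
    """
    freqs = spec.freqs
    sel = (freqs >= band.lo) & (freqs <= band.hi)
    if not sel.any():
        raise ValueError(f"band {band.name} [{band.lo}, {band.hi}] Hz empty on this grid")
    if isinstance(spec, PSD):
        vals = spec.density[sel]
        if mode == "mean":
            return float(vals.mean())
        if mode == "integral":
            return float(np.trapezoid(vals, freqs[sel]))
        raise ValueError(f"unknown mode {mode!r}")
    vals = spec.power[:, sel]
    if mode == "mean":
        return vals.mean(axis=1)
    if mode == "integral":
        return np.trapezoid(vals, freqs[sel], axis=1)
    raise ValueError(f"unknown mode {mode!r}")


def _event_band_series(
    trace: SignalTrace,
    onset: float,
    pre_s: float,
    post_s: float,
    band: BandDefinition,
    window_s: float,
) -> tuple:
    """Band-power time series around one event, aligned so a window edge
    falls exactly at the event onset."""
    fs = trace.sampling_rate
    seg = trace.segment(onset - pre_s, onset + post_s)
    spec = spectrogram(SignalTrace(seg, fs), window_s=window_s)
    series = band_power(spec, band, mode="mean")
    times = spec.times - pre_s
    return times, series


def peri_event_band_timecourse(
    trace: SignalTrace,
    events: EventSet,
    band: BandDefinition = SWA,
    pre_s: float = 60.0,
    post_s: float = 60.0,
    baseline: Interval = Interval(-50.0, 30.0),
    window_s: float = 0.5,
):
    """Event-averaged band-power time course as percent change from baseline.

    For each event the band power is computed from a 500-ms spectrogram of
    the window ``[onset - pre_s, onset + post_s)`` and expressed as
    ``100 * (x - B) / B`` with ``B`` the mean over the ``baseline`` interval
    (given relative to onset, e.g. ``Interval(-50, 30)`` for the 20-to-50-s
    pre-event baseline).  Returns ``(times, mean, sem)``; the baseline window
    is an explicit parameter because different analyses use different ones.
    """
    if len(events) == 0:
        raise ValueError("no events")
    all_series = []
    times = None
    for ev in events:
        t, series = _event_band_series(trace, ev.onset, pre_s, post_s, band, window_s)
        bsel = (t >= baseline.onset) & (t < baseline.offset)
        if not bsel.any():
            raise ValueError("baseline window contains no spectrogram bins")
        b = series[bsel].mean()
        if b <= 0:
            raise ValueError("non-positive baseline band power")
        all_series.append(100.0 * (series - b) / b)
        times = t
    arr = np.vstack(all_series)
    mean = arr.mean(axis=0)
    sem = (
        arr.std(axis=0, ddof=1) / np.sqrt(arr.shape[0])
        if arr.shape[0] > 1
        else np.zeros(arr.shape[1])
    )
    return times, mean, sem


def psd_before_during_after(
    trace: SignalTrace,
    events: EventSet,
    before: Interval = Interval(-50.0, 20.0),
    during: Interval = Interval(0.0, 2.0),
    after: Interval = Interval(5.0, 5.0),
    resolution_hz: float = 0.5,
    auc_band: tuple = (0.5, 8.5),
):
    """Event-averaged PSDs before / during / after arousals.

    Default windows relative to onset: before = [-50, -30) s, during =
    [0, 2) s, after = [5, 10) s.  Returns a dict with the three PSDs
    (averaged across events), the per-bin percent change
    ``100 * (after - before) / before`` and its trapezoidal area under the
    curve over ``auc_band`` (0.5-8.5 Hz by default).  Events lacking context
    are skipped with a log entry; if all are skipped an error is raised.
    """
    if len(events) == 0:
        raise ValueError("no events")
    fs = trace.sampling_rate
    acc = {"before": [], "during": [], "after": []}
    windows = {"before": before, "during": during, "after": after}
    n_used = 0
    freqs = None
    for ev in events:
        try:
            segs = {
                name
                : trace.segment(ev.onset + w.onset, ev.onset + w.offset)
                for name, w in windows.items()
            }
            psds = {
                name: welch_psd(SignalTrace(seg, fs), resolution_hz)
                for name, seg in segs.items()
            }
        except ValueError as exc:
            log.info("skipping event at %.1f s: %s", ev.onset, exc)
            continue
        for name, psd in psds.items():
            acc[name].append(psd.density)
        freqs = psds["before"].freqs
        n_used += 1
    if n_used == 0:
        raise ValueError("no event had sufficient context")
    mean_psd = {name: PSD(freqs, np.vstack(v).mean(axis=0)) for name, v in acc.items()}
    b = mean_psd["before"].density
    a = mean_psd["after"].density
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where(b > 0, 100.0 * (a - b) / b, np.nan)
    sel = (freqs >= auc_band[0]) & (freqs <= auc_band[1])
    auc = float(np.trapezoid(pct[sel], freqs[sel]))
    return {
        "before": mean_psd["before"],
        "during": mean_psd["during"],
        "after": mean_psd["after"],
        "percent_change": PSD(freqs, pct),
        "auc": auc,
        "n_events": n_used,
    }


def post_ma_swa(
    trace: SignalTrace,
    event,
    baseline_swa: float,
    window: Interval = Interval(3.0, 5.0),
    band: BandDefinition = SWA,
) -> float:
    """Post-arousal SWA as percent of a recording-level baseline.

    Mean SWA band power in ``[onset + 3, onset + 8)`` (default) divided by
    ``baseline_swa`` (typically NREM SWA over the baseline light phase),
    times 100.
    """
    if baseline_swa <= 0:
        raise ValueError("baseline_swa must be positive")
    fs = trace.sampling_rate
    seg = trace.segment(event.onset + window.onset, event.onset + window.offset)
    spec = spectrogram(SignalTrace(seg, fs), window_s=0.5)
    return 100.0 * float(band_power(spec, band, mode="mean").mean()) / baseline_swa


def nrem_swa_baseline(
    trace: SignalTrace,
    hyp: Hypnogram,
    window: Optional[Interval] = None,
    band: BandDefinition = SWA,
) -> float:
    """Mean SWA band power over NREM epochs, optionally restricted to a
    window (e.g. the first 6 h of lights-on of the baseline day).

    Used to normalize peri-event SWA to a per-recording baseline.
    """
    total, weight = 0.0, 0.0
    for ep in state_episodes(hyp, NREM):
        lo, hi = ep.onset, ep.offset
        if window is not None:
            lo, hi = max(lo, window.onset), min(hi, window.offset)
        if hi - lo < 2.0:  # need at least a few 500-ms windows
            continue
        seg = trace.segment(lo, hi)
        spec = spectrogram(SignalTrace(seg, trace.sampling_rate), window_s=0.5)
        p = band_power(spec, band, mode="mean")
        total += p.sum()
        weight += p.size
    if weight == 0:
        raise ValueError("no NREM available for baseline SWA")
    return total / weight
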