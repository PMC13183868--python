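"""Multi-unit firing-rate analysis around arousal events.

Multi-unit activity arrives as per-channel spike-time lists (16 channels
spanning the cortical column in the source recordings).  Rates are counted
in 1-s bins; peri-event matrices are built time-locked to event onsets.
Two normalizations are provided: percent change of the pooled rate from the
[-20, -10) s pre-event baseline, and per-channel z-scoring against a
reference condition (SD over the reference's event-averaged trace, mean over
its first 10 s).  Channels are classified as increased/decreased when the
event-averaged trace exceeds the pre-event baseline mean by k standard
deviations inside the [-5, +5) s search window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .core import EventSet, Interval

__all__ = [
    "SpikeTrains",
    "PeriEventMatrix",
    "ChannelClassification",
    "bin_spike_rate",
    "peri_event_rates",
    "pooled_peri_event_percent",
    "normalize_channel_rates",
    "classify_channels",
    "channel_excursion_metrics",
]


@dataclass
class SpikeTrains:
    """Per-channel spike-time lists (seconds from recording start)."""

    trains: list
    duration_s: float
    channel_labels: Optional[list] = None

    def __post_init__(self) -> None:
        self.trains = [np.sort(np.asarray(t, dtype=float)) for t in self.trains]
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        for i, t in enumerate(self.trains):
            if t.size and (t[0] < 0 or t[-1] > self.duration_s):
                raise ValueError(f"channel {i}: spikes outside recording span")

    @property
    def n_channels(self) -> int:
        return len(self.trains)

    @property
    def n_spikes(self) -> int:
        return int(sum(t.size for t in self.trains))


@dataclass
class PeriEventMatrix:
    """Event-locked rate array: ``rates[event, bin]`` or
    ``rates[event, bin, channel]``.

    ``t0_offset`` is the time of the first bin's left edge relative to event
    onset (e.g. -20.0 for a [-20, +20) s window at ``bin_s`` = 1).
    """

    rates: np.ndarray
    bin_s: float
    t0_offset: float

    @property
    def n_events(self) -> int:
        return self.rates.shape[0]

    @property
    def n_bins(self) -> int:
        return self.rates.shape[1]

    @property
    def n_channels(self) -> int:
        return self.rates.shape[2] if self.rates.ndim == 3 else 1

    def bin_centers(self) -> np.ndarray:
        return self.t0_offset + (np.arange(self.n_bins) + 0.5) * self.bin_s

    def bin_mask(self, window: Interval) -> np.ndarray:
        """Bins whose left edge falls inside ``window`` (relative to onset)."""
        left = self.t0_offset + np.arange(self.n_bins) * self.bin_s
        return (left >= window.onset) & (left < window.offset)

    def event_average(self) -> np.ndarray:
        """Average across events -> ``[bin]`` or ``[bin, channel]``."""
        return self.rates.mean(axis=0)


@dataclass
class ChannelClassification:
    """Per-channel increased/decreased/unclassified labels plus the
    criterion used."""

    labels: list
    criterion_k_sd: float
    baseline_window: Interval
    search_window: Interval
    excursions_sd: np.ndarray = field(default=None)

    def count(self, label: str) -> int:
        return sum(1 for lab in self.labels if lab == label)


def bin_spike_rate(trains: SpikeTrains, bin_s: float = 1.0):
    """Firing rate in fixed bins, per channel and pooled across channels.

    Returns ``(per_channel, pooled, edges)`` with ``per_channel`` of shape
    ``(n_channels, n_bins)`` in spikes/s and ``pooled`` the channel sum
    (the combined number of spikes from all channels per second).
    """
    if bin_s <= 0:
        raise ValueError("bin_s must be positive")
    n_bins = int(np.ceil(trains.duration_s / bin_s))
    if n_bins == 0:
        raise ValueError("empty recording span")
    edges = np.arange(n_bins + 1) * bin_s
    per_channel = np.empty((trains.n_channels, n_bins))
    for i, t in enumerate(trains.trains):
        counts, _ = np.histogram(t, bins=edges)
        per_channel[i] = counts / bin_s
    pooled = per_channel.sum(axis=0)
    return per_channel, pooled, edges


def peri_event_rates(
    trains: SpikeTrains,
    events: EventSet,
    window: Interval = Interval(-20.0, 40.0),
    bin_s: float = 1.0,
    pooled: bool = False,
) -> PeriEventMatrix:
    """Event-locked rate matrix.

    ``window`` is relative to event onset (default [-20, +20) s).  With
    ``pooled=True`` the channels are summed first.  Events whose window
    leaves the recording raise an error — filter those upstream.
    """
    if len(events) == 0:
        raise ValueError("no events")
    n_bins = int(round(window.duration / bin_s))
    rel_edges = window.onset + np.arange(n_bins + 1) * bin_s
    shape = (len(events), n_bins) if pooled else (len(events), n_bins, trains.n_channels)
    rates = np.zeros(shape)
    for k, ev in enumerate(events):
        edges = ev.onset + rel_edges
        if edges[0] < 0 or edges[-1] > trains.duration_s:
            raise ValueError(f"event at {ev.onset:.1f} s lacks peri-event context")
        for c, t in enumerate(trains.trains):
            counts, _ = np.histogram(t, bins=edges)
            if pooled:
                rates[k] += counts / bin_s
            else:
                rates[k, :, c] = counts / bin_s
    return PeriEventMatrix(rates=rates, bin_s=bin_s, t0_offset=window.onset)


def pooled_peri_event_percent(
    trains: SpikeTrains,
    events: EventSet,
    window: Interval = Interval(-20.0, 40.0),
    bin_s: float = 1.0,
    baseline: Interval = Interval(-20.0, 10.0),
):
    """Pooled peri-event rate as percent change from the pre-event baseline.

    The pooled (channel-summed) rate is averaged across events and expressed
    as ``100 * (x - B) / B`` with ``B`` the mean over ``baseline`` (default
    the first 10 s of the trace, i.e. 10-20 s before the event).  The SEM is
    the across-event SEM on the same percent scale.  Invariant to uniform
    rescaling of all firing rates.
    """
    peri = peri_event_rates(trains, events, window=window, bin_s=bin_s, pooled=True)
    bsel = peri.bin_mask(baseline)
    if not bsel.any():
        raise ValueError("baseline window contains no bins")
    avg = peri.event_average()
    b = avg[bsel].mean()
    if b <= 0:
        raise ValueError("non-positive baseline rate")
    mean = 100.0 * (avg - b) / b
    if peri.n_events > 1:
        sem = 100.0 * peri.rates.std(axis=0, ddof=1) / np.sqrt(peri.n_events) / b
    else:
        sem = np.zeros_like(mean)
    return peri.bin_centers(), mean, sem


def normalize_channel_rates(
    peri: PeriEventMatrix,
    reference: PeriEventMatrix,
    baseline: Interval = Interval(-20.0, 10.0),
) -> np.ndarray:
    """Z-score event-averaged channel traces against a reference condition.

    Per channel, the SD is taken over the *reference* condition's
    event-averaged trace and the mean over its first 10 s (``baseline``
    relative to onset); every condition is then transformed as
    ``(x - mean) / SD``.  Returns the normalized event-averaged traces of
    ``peri``, shape ``(n_bins, n_channels)``.
    """
    if peri.rates.ndim != 3 or reference.rates.ndim != 3:
        raise ValueError("per-channel matrices required")
    ref_avg = reference.event_average()  # [bin, channel]
    bsel = reference.bin_mask(baseline)
    if not bsel.any():
        raise ValueError("baseline window contains no bins")
    sd = ref_avg.std(axis=0, ddof=0)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise ValueError(f"zero reference SD on channel(s) {zero.tolist()}")
    mean = ref_avg[bsel].mean(axis=0)
    return (peri.event_average() - mean) / sd


def classify_channels(
    peri: PeriEventMatrix,
    k_sd: float = 5.0,
    baseline: Interval = Interval(-15.0, 10.0),
    search: Interval = Interval(-5.0, 10.0),
) -> ChannelClassification:
    """Label channels as increased / decreased / unclassified.

    Operates on the event-averaged trace of each channel.  A channel is
    *decreased* when its minimum inside ``search`` ([-5, +5) s by default)
    falls below ``mean(baseline) - k_sd * SD(baseline)`` (baseline
    [-15, -5) s), *increased* when its maximum exceeds
    ``mean(baseline) + k_sd * SD(baseline)``.  If both criteria fire, the
    larger absolute excursion in SD units decides.  A degenerate baseline
    (SD = 0) leaves the channel unclassified with a warning.

    ``k_sd`` = 5 is the strict criterion for sleep-pressure comparisons;
    ``k_sd`` = 2 the permissive one for duration comparisons.
    """
    if peri.rates.ndim != 3:
        raise ValueError("per-channel matrix required")
    bsel = peri.bin_mask(baseline)
    ssel = peri.bin_mask(search)
    if not bsel.any() or not ssel.any():
        raise ValueError("baseline/search window outside peri-event grid")
    avg = peri.event_average()  # [bin, channel]
    labels = []
    excursions = np.zeros(peri.n_channels)
    for c in range(peri.n_channels):
        base = avg[bsel, c]
        # sample SD: the baseline window is short (10 bins), so the unbiased
        # estimator matters for the criterion's specificity
        m, sd = base.mean(), base.std(ddof=1)
        if sd == 0:
            warnings.warn(f"channel {c}: zero baseline SD, left unclassified")
            labels.append("unclassified")
            continue
        lo = (avg[ssel, c].min() - m) / sd
        hi = (avg[ssel, c].max() - m) / sd
        inc, dec = hi > k_sd, lo < -k_sd
        if inc and dec:
            label = "increased" if hi >= -lo else "decreased"
            excursions[c] = hi if hi >= -lo else lo
        elif inc:
            label, excursions[c] = "increased", hi
        elif dec:
            label, excursions[c] = "decreased", lo
        else:
            label = "unclassified"
            excursions[c] = hi if hi >= -lo else lo
        labels.append(label)
    return ChannelClassification(
        labels=labels,
        criterion_k_sd=k_sd,
        baseline_window=baseline,
        search_window=search,
        excursions_sd=excursions,
    )


def channel_excursion_metrics(
    peri: PeriEventMatrix,
    pre: Interval = Interval(-5.0, 5.0),
    post: Interval = Interval(0.0, 5.0),
):
    """Per-channel pre-onset maximum and post-onset minimum.

    On the event-averaged trace: the maximum rate in [-5, 0) s before onset,
    the minimum in [0, +5) s after, and their latencies (bin centers).
    Returns a dict of arrays keyed ``max_before``, ``max_latency``,
    ``min_after``, ``min_latency``.
    """
    if peri.rates.ndim != 3:
        raise ValueError("per-channel matrix required")
    presel = peri.bin_mask(pre)
    postsel = peri.bin_mask(post)
    if not presel.any() or not postsel.any():
        raise ValueError("windows outside peri-event grid")
    avg = peri.event_average()
    centers = peri.bin_centers()
    pre_avg, post_avg = avg[presel], avg[postsel]
    imax = pre_avg.argmax(axis=0)
    imin = post_avg.argmin(axis=0)
    return {
        "max_before": pre_avg.max(axis=0),
        "max_latency": centers[presel][imax],
        "min_after": post_avg.min(axis=0),
        "min_latency": centers[postsel][imin],
    }
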