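"""Shared data containers: signal traces, time intervals, and event sets.

All times are in seconds from recording start; intervals are half-open
``[onset, onset + duration)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

__all__ = ["SignalTrace", "Interval", "Event", "EventSet"]


@dataclass
class SignalTrace:
    """Uniformly sampled single-channel time series.

    Parameters
    ----------
    samples : array-like
        Signal values.
    sampling_rate : float
        Samples per second (Hz), must be positive.
    label : str
        Channel name, e.g. ``"EMG"`` or ``"LFP_L5"``.
    unit : str
        Physical unit label (informational).
    """

    samples: np.ndarray
    sampling_rate: float
    label: str = ""
    unit: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("SignalTrace samples must be one-dimensional")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("SignalTrace samples must be finite")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sampling_rate

    def times(self) -> np.ndarray:
        """Sample times in seconds from recording start."""
        return np.arange(self.samples.size) / self.sampling_rate

    def segment(self, t0: float, t1: float) -> np.ndarray:
        """Samples in the half-open window ``[t0, t1)``.

        Raises ``ValueError`` when the window extends beyond the recording.
        """
        i0 = int(round(t0 * self.sampling_rate))
        i1 = int(round(t1 * self.sampling_rate))
        if i0 < 0 or i1 > self.samples.size or i1 < i0:
            raise ValueError(
                f"window [{t0}, {t1}) outside recording of {self.duration_s:.1f} s"
            )
        return self.samples[i0:i1]


@dataclass(frozen=True)
class Interval:
    """Half-open time interval ``[onset, onset + duration)`` in seconds."""

    onset: float
    duration: float

    def __post_init__(self) -> None:
        if self.duration < 0:
            raise ValueError("duration must be >= 0")

    @property
    def offset(self) -> float:
        return self.onset + self.duration

    @property
    def midpoint(self) -> float:
        return self.onset + self.duration / 2.0

    def overlap(self, other: "Interval") -> float:
        """Length of the intersection with ``other`` (seconds, >= 0)."""
        lo = max(self.onset, other.onset)
        hi = min(self.offset, other.offset)
        return max(0.0, hi - lo)

    def contains_time(self, t: float) -> bool:
        return self.onset <= t < self.offset


# Event kinds recognised by the detector.
NREM_MA = "nrem_ma"
REM_MA = "rem_ma"
WAKE_TRANSITION = "wake_transition"
EVENT_KINDS = (NREM_MA, REM_MA, WAKE_TRANSITION)


@dataclass(frozen=True)
class Event:
    """A detected arousal event.

    ``kind`` is one of ``nrem_ma`` (micro-arousal inside NREM sleep),
    ``rem_ma`` (micro-arousal within the window after REM termination) or
    ``wake_transition`` (muscle-activity bout > 20 s, an awakening).
    ``peak_amplitude`` is the maximum of the rectified-EMG envelope inside
    the event, in envelope units.
    """

    onset: float
    duration: float
    kind: str = NREM_MA
    peak_amplitude: float = float("nan")

    def __post_init__(self) -> None:
        if self.duration < 0:
            raise ValueError("duration must be >= 0")
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")

    @property
    def offset(self) -> float:
        return self.onset + self.duration

    @property
    def midpoint(self) -> float:
        return self.onset + self.duration / 2.0

    def interval(self) -> Interval:
        return Interval(self.onset, self.duration)


@dataclass
class EventSet:
    """Ordered collection of detected events.

    Events are kept sorted by onset; overlapping events are rejected at
    construction (the detector's merge step guarantees disjointness).
    """

    events: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: e.onset)
        for a, b in zip(self.events, self.events[1:]):
            if b.onset < a.offset:
                raise ValueError("events overlap")

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self) -> Iterator[Event]:
        return iter(self.events)

    def __getitem__(self, i):
        return self.events[i]

    @property
    def onsets(self) -> np.ndarray:
        return np.array([e.onset for e in self.events])

    @property
    def durations(self) -> np.ndarray:
        return np.array([e.duration for e in self.events])

    def of_kind(self, kind: str) -> "EventSet":
        return EventSet([e for e in self.events if e.kind == kind])


def merge_intervals(intervals: Sequence[Interval], max_gap: float) -> list:
    """Merge sorted intervals whose silent gap (next.onset - prev.offset)
    is strictly below ``max_gap`` into single spanning intervals."""
    if not intervals:
        return []
    out = [intervals[0]]
    for iv in intervals[1:]:
        prev = out[-1]
        if iv.onset - prev.offset < max_gap:
            hi = max(prev.offset, iv.offset)
            out[-1] = Interval(prev.onset, hi - prev.onset)
        else:
            out.append(iv)
    return out
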