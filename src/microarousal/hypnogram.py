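"""Epoch-based vigilance-state model.

A hypnogram is a sequence of 4-s epoch labels drawn from {W, N, R}
(wake, NREM sleep, REM sleep), anchored to the recording start.  This
module provides rescoring of short wake/REM intrusions inside NREM
(the first step of the micro-arousal detector), run-length episode and
bout extraction, time-in-state queries, and the circadian sleep-pressure
window definitions used to group arousals.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import Interval

__all__ = [
    "Hypnogram",
    "SleepPressureWindows",
    "rescore_short_intrusions",
    "state_episodes",
    "state_bouts",
    "fraction_in_state",
    "sleep_pressure_windows",
    "read_hypnogram",
    "write_hypnogram",
]

STATES = ("W", "N", "R")
WAKE, NREM, REM = STATES

# Numeric-code mapping tolerated by the plain-text reader (1=W, 2=N, 3=R,
# the common rodent scoring-software convention).
DEFAULT_NUMERIC_CODES = {"1": "W", "2": "N", "3": "R"}


@dataclass
class Hypnogram:
    """Vigilance-state labels on a fixed epoch grid.

    Parameters
    ----------
    labels : sequence of {"W", "N", "R"}
        One label per epoch.
    epoch_s : float
        Epoch length in seconds (4 s is the scoring convention here).
    start_time : float
        Time of the first epoch's left edge, seconds from recording origin.
    """

    labels: np.ndarray
    epoch_s: float = 4.0
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype="U1")
        if self.epoch_s <= 0:
            raise ValueError("epoch_s must be positive")
        if self.labels.size == 0:
            raise ValueError("empty hypnogram")
        bad = set(np.unique(self.labels)) - set(STATES)
        if bad:
            raise ValueError(f"unknown state codes: {sorted(bad)}")

    @property
    def n_epochs(self) -> int:
        return self.labels.size

    @property
    def duration_s(self) -> float:
        return self.n_epochs * self.epoch_s

    @property
    def end_time(self) -> float:
        return self.start_time + self.duration_s

    def state_at(self, t: float) -> str:
        """State label at time ``t`` (seconds on the recording timeline)."""
        idx = int(np.floor((t - self.start_time) / self.epoch_s))
        if idx < 0 or idx >= self.n_epochs:
            raise ValueError(f"time {t} outside hypnogram span")
        return str(self.labels[idx])

    def states_at(self, t: np.ndarray) -> np.ndarray:
        idx = np.floor((np.asarray(t) - self.start_time) / self.epoch_s).astype(int)
        if np.any(idx < 0) or np.any(idx >= self.n_epochs):
            raise ValueError("times outside hypnogram span")
        return self.labels[idx]

    def sample_mask(self, state: str, sampling_rate: float, n_samples: int) -> np.ndarray:
        """Boolean per-sample mask for a signal aligned to this hypnogram.

        Samples beyond the hypnogram's span are False.
        """
        _check_state(state)
        t = self.start_time + np.arange(self.n_epochs) * self.epoch_s
        mask = np.zeros(n_samples, dtype=bool)
        in_state = self.labels == state
        i0 = np.round(t * sampling_rate).astype(int)
        i1 = np.round((t + self.epoch_s) * sampling_rate).astype(int)
        for a, b, keep in zip(i0, i1, in_state):
            if keep:
                mask[max(a, 0) : min(b, n_samples)] = True
        return mask

    def copy(self) -> "Hypnogram":
        return Hypnogram(self.labels.copy(), self.epoch_s, self.start_time)


def _check_state(state: str) -> None:
    if state not in STATES:
        raise ValueError(f"unknown state code {state!r}; expected one of {STATES}")


def _runs(labels: np.ndarray):
    """Yield (start_idx, stop_idx, label) for maximal constant runs."""
    n = labels.size
    start = 0
    for i in range(1, n + 1):
        if i == n or labels[i] != labels[start]:
            yield start, i, labels[start]
            start = i


def rescore_short_intrusions(hyp: Hypnogram, max_intrusion_s: float = 11.0) -> Hypnogram:
    """Relabel brief wake/REM intrusions inside NREM sleep as NREM.

    Any maximal run of W or R epochs (mixed W/R runs count as a single
    intrusion) that is flanked by NREM on *both* sides and whose duration is
    strictly below ``max_intrusion_s`` (default 11 s) is rescored as N.  This
    removes manually scored micro-arousals so the detector starts from
    continuous NREM.  Runs touching the recording boundary, or bounded by a
    non-NREM state on either side, are never rescored.

    The operation is idempotent and never changes an N label.
    """
    if max_intrusion_s <= 0:
        raise ValueError("max_intrusion_s must be positive")
    labels = hyp.labels.copy()
    non_nrem = labels != NREM
    # maximal runs of non-NREM labels
    n = labels.size
    start = 0
    for i in range(1, n + 1):
        if i == n or non_nrem[i] != non_nrem[start]:
            if non_nrem[start]:
                dur = (i - start) * hyp.epoch_s
                interior = start > 0 and i < n
                if interior and dur < max_intrusion_s:
                    # both flanks are N by construction of the runs
                    labels[start:i] = NREM
            start = i
    return Hypnogram(labels, hyp.epoch_s, hyp.start_time)


def state_episodes(hyp: Hypnogram, state: str) -> list:
    """Maximal runs of ``state`` as half-open intervals on the recording
    timeline; across the three states the episodes tile the recording."""
    _check_state(state)
    out = []
    for a, b, lab in _runs(hyp.labels):
        if lab == state:
            onset = hyp.start_time + a * hyp.epoch_s
            out.append(Interval(onset, (b - a) * hyp.epoch_s))
    return out


def state_bouts(hyp: Hypnogram, state: str, min_duration_s: float) -> list:
    """Episodes of ``state`` strictly longer than ``min_duration_s``."""
    if min_duration_s < 0:
        raise ValueError("min_duration_s must be >= 0")
    return [iv for iv in state_episodes(hyp, state) if iv.duration > min_duration_s]


def fraction_in_state(hyp: Hypnogram, window: Interval, state: str) -> float:
    """Fraction of ``window`` spent in ``state``.

    Partial epoch overlap is counted proportionally.  Raises if the window
    does not intersect the hypnogram span or has zero duration.
    """
    _check_state(state)
    if window.duration <= 0:
        raise ValueError("window must have positive duration")
    lo = max(window.onset, hyp.start_time)
    hi = min(window.offset, hyp.end_time)
    if hi <= lo:
        raise ValueError("window out of range")
    # epoch indices overlapped by [lo, hi)
    i0 = int(np.floor((lo - hyp.start_time) / hyp.epoch_s))
    i1 = int(np.ceil((hi - hyp.start_time) / hyp.epoch_s))
    total = 0.0
    for i in range(i0, min(i1, hyp.n_epochs)):
        if hyp.labels[i] != state:
            continue
        a = hyp.start_time + i * hyp.epoch_s
        b = a + hyp.epoch_s
        total += max(0.0, min(b, hi) - max(a, lo))
    return total / window.duration


@dataclass(frozen=True)
class SleepPressureWindows:
    """The three circadian windows used to group arousals by sleep pressure.

    ``low``    — last 2 h of the baseline light phase (pressure dissipated);
    ``medium`` — first 2 h of the baseline light phase;
    ``high``   — first 2 h of recovery sleep after 6 h sleep deprivation.
    """

    low: Interval
    medium: Interval
    high: Interval
    lights_on: float
    sd_duration: float = 21600.0


def sleep_pressure_windows(
    lights_on: float,
    sd_end: float,
    light_period_s: float = 43200.0,
    window_s: float = 7200.0,
) -> SleepPressureWindows:
    """Build the low/medium/high sleep-pressure windows.

    Parameters
    ----------
    lights_on : float
        Light onset of the baseline day, seconds on the recording timeline.
    sd_end : float
        End of the 6-h sleep deprivation (start of recovery sleep).
    light_period_s : float
        Length of the light phase (12 h by default).
    window_s : float
        Width of each grouping window (2 h by default).
    """
    if lights_on < 0 or sd_end < 0:
        raise ValueError("times must be non-negative")
    if sd_end < lights_on:
        raise ValueError("sd_end must not precede lights_on")
    medium = Interval(lights_on, window_s)
    low = Interval(lights_on + light_period_s - window_s, window_s)
    high = Interval(sd_end, window_s)
    return SleepPressureWindows(low=low, medium=medium, high=high, lights_on=lights_on)


# ---------------------------------------------------------------------------
# Plain-text hypnogram format: one label per line, header lines
#   #epoch_length_s=4
#   #start_time_s=0
# Numeric codes (1/2/3) are tolerated and mapped via ``numeric_codes``.
# ---------------------------------------------------------------------------


def write_hypnogram(hyp: Hypnogram, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#epoch_length_s={hyp.epoch_s:g}\n")
        fh.write(f"#start_time_s={hyp.start_time:g}\n")
        fh.write("\n".join(hyp.labels))
        fh.write("\n")


def read_hypnogram(path, numeric_codes: dict | None = None) -> Hypnogram:
    codes = dict(DEFAULT_NUMERIC_CODES)
    if numeric_codes:
        codes.update({str(k): v for k, v in numeric_codes.items()})
    epoch_s, start_time = 4.0, 0.0
    labels = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].partition("=")
                if key == "epoch_length_s":
                    epoch_s = float(val)
                elif key == "start_time_s":
                    start_time = float(val)
                continue
            labels.append(codes.get(line, line))
    return Hypnogram(np.array(labels), epoch_s=epoch_s, start_time=start_time)
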