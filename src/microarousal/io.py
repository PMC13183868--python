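"""Readers/writers and resampling.

Recording bundles are stored as a self-describing directory: signals as
``.npy`` arrays with a JSON sidecar carrying sampling rates and metadata,
the hypnogram in the plain-text one-label-per-line format, spike trains as
``channel<TAB>time_s`` text, and planted ground truth as TSV.  EDF/EDF+
input is supported through :func:`read_edf` (via ``mne``); signals from any
source are brought to the 256-Hz working rate with :func:`resample`.

Event sets round-trip through a TSV with header
``onset_s  duration_s  kind  peak_amplitude`` and can additionally be
exported BED-like (recording id, 0-based half-open sample coordinates).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from fractions import Fraction
from pathlib import Path
from typing import Optional

import numpy as np
from scipy import signal as sps

from .core import Event, EventSet, SignalTrace
from .firing import SpikeTrains
from .hypnogram import Hypnogram, read_hypnogram, write_hypnogram
from .synthetic import GroundTruth, PlantedBurst, RecordingBundle, SyntheticConfig

__all__ = [
    "read_edf",
    "resample",
    "write_events",
    "read_events",
    "write_events_bed",
    "write_bundle",
    "read_bundle",
    "content_hash",
]

log = logging.getLogger(__name__)


def read_edf(path) -> dict:
    """Read all signal channels of an EDF/EDF+ file.

    Returns ``{label: SignalTrace}``; each channel keeps its own sampling
    rate.  Annotation channels are ignored with a log line.  Requires the
    optional ``mne`` dependency.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise ImportError("EDF support requires the 'mne' package") from exc
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    if raw.annotations is not None and len(raw.annotations):
        log.info("ignoring %d EDF annotations", len(raw.annotations))
    out = {}
    for name in raw.ch_names:
        pick = raw.copy().pick([name])
        fs = float(pick.info["sfreq"])
        data = pick.get_data()[0]
        out[name] = SignalTrace(data, fs, label=name)
    return out


def resample(trace: SignalTrace, target_hz: float = 256.0) -> SignalTrace:
    """Polyphase resampling to ``target_hz``.

    Identity when the rate already matches.  Band-limited content below the
    smaller Nyquist is preserved; duration is preserved to within one sample
    period.
    """
    if target_hz <= 0:
        raise ValueError("target_hz must be positive")
    if abs(trace.sampling_rate - target_hz) < 1e-9:
        return trace
    frac = Fraction(target_hz / trace.sampling_rate).limit_denominator(10000)
    y = sps.resample_poly(trace.samples, frac.numerator, frac.denominator)
    return SignalTrace(y, target_hz, label=trace.label, unit=trace.unit)


# ---------------------------------------------------------------------------
# events
# ---------------------------------------------------------------------------

EVENTS_HEADER = "onset_s\tduration_s\tkind\tpeak_amplitude"


def write_events(events: EventSet, path) -> None:
    with open(path, "w") as fh:
        fh.write(EVENTS_HEADER + "\n")
        for e in events:
            fh.write(f"{e.onset:.6f}\t{e.duration:.6f}\t{e.kind}\t{e.peak_amplitude:.6g}\n")


def read_events(path) -> EventSet:
    events = []
    with open(path) as fh:
        header = fh.readline().strip()
        if header != EVENTS_HEADER:
            raise ValueError(f"unexpected events header: {header!r}")
        for line in fh:
            if not line.strip():
                continue
            onset, duration, kind, peak = line.rstrip("\n").split("\t")
            events.append(
                Event(float(onset), float(duration), kind=kind, peak_amplitude=float(peak))
            )
    return EventSet(events)


def write_events_bed(events: EventSet, path, recording_id: str, sampling_rate: float) -> None:
    """BED-like 3+1 column export: recording id, start/end in 0-based
    half-open *sample* coordinates, event kind."""
    with open(path, "w") as fh:
        for e in events:
            i0 = int(round(e.onset * sampling_rate))
            i1 = int(round(e.offset * sampling_rate))
            fh.write(f"{recording_id}\t{i0}\t{i1}\t{e.kind}\n")


# ---------------------------------------------------------------------------
# spike trains
# ---------------------------------------------------------------------------


def write_spikes(spikes: SpikeTrains, path) -> None:
    """One spike per line: ``channel<TAB>time_s``."""
    with open(path, "w") as fh:
        fh.write("#duration_s=%g\n" % spikes.duration_s)
        fh.write("#n_channels=%d\n" % spikes.n_channels)
        for c, train in enumerate(spikes.trains):
            for t in train:
                fh.write(f"{c}\t{t:.6f}\n")


def read_spikes(path) -> SpikeTrains:
    duration = None
    n_channels = None
    per_channel: dict = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].partition("=")
                if key == "duration_s":
                    duration = float(val)
                elif key == "n_channels":
                    n_channels = int(val)
                continue
            c, t = line.split("\t")
            per_channel.setdefault(int(c), []).append(float(t))
    if duration is None:
        raise ValueError("spike file lacks #duration_s header")
    n = n_channels if n_channels is not None else (max(per_channel) + 1 if per_channel else 0)
    trains = [np.array(per_channel.get(c, [])) for c in range(n)]
    return SpikeTrains(trains=trains, duration_s=duration)


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

TRUTH_HEADER = "onset_s\tduration_s\tgroup\tsatisfies_rules\tsource"


def write_truth(truth: GroundTruth, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#post_swa_intercept={truth.post_swa_intercept:g}\n")
        fh.write(f"#post_swa_slope={truth.post_swa_slope:g}\n")
        if truth.channel_labels:
            fh.write("#channel_labels=" + ",".join(truth.channel_labels) + "\n")
        fh.write(TRUTH_HEADER + "\n")
        for b in truth.bursts:
            fh.write(
                f"{b.onset:.6f}\t{b.duration:.6f}\t{b.group}\t"
                f"{int(b.satisfies_rules)}\t{b.source}\n"
            )


def read_truth(path) -> GroundTruth:
    truth = GroundTruth()
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                key, _, val = line[1:].partition("=")
                if key == "post_swa_intercept":
                    truth.post_swa_intercept = float(val)
                elif key == "post_swa_slope":
                    truth.post_swa_slope = float(val)
                elif key == "channel_labels":
                    truth.channel_labels = val.split(",")
                continue
            if line == TRUTH_HEADER:
                continue
            onset, duration, group, ok, source = line.split("\t")
            truth.bursts.append(
                PlantedBurst(
                    onset=float(onset),
                    duration=float(duration),
                    group=int(group),
                    satisfies_rules=bool(int(ok)),
                    source=source,
                )
            )
    return truth


# ---------------------------------------------------------------------------
# bundle directory
# ---------------------------------------------------------------------------


def _config_to_json(cfg: SyntheticConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["channel_effect_profiles"] = [list(p) for p in d["channel_effect_profiles"]]
    return d


def _config_from_json(d: dict) -> SyntheticConfig:
    d = dict(d)
    d["channel_effect_profiles"] = tuple(tuple(p) for p in d["channel_effect_profiles"])
    if d.get("sd_block") is not None:
        d["sd_block"] = tuple(d["sd_block"])
    d["burst_duration_range_s"] = tuple(d["burst_duration_range_s"])
    d["post_window"] = tuple(d["post_window"])
    return SyntheticConfig(**d)


def write_bundle(bundle: RecordingBundle, directory) -> Path:
    """Write a recording bundle to a self-describing directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.save(directory / "emg.npy", bundle.emg.samples)
    np.save(directory / "lfp.npy", bundle.lfp.samples)
    write_hypnogram(bundle.hyp, directory / "hypnogram.txt")
    write_spikes(bundle.spikes, directory / "spikes.tsv")
    write_truth(bundle.truth, directory / "truth.tsv")
    meta = {
        "emg": {"sampling_rate": bundle.emg.sampling_rate, "unit": bundle.emg.unit},
        "lfp": {"sampling_rate": bundle.lfp.sampling_rate, "unit": bundle.lfp.unit},
        "config": _config_to_json(bundle.config),
    }
    with open(directory / "meta.json", "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)
    return directory


def read_bundle(directory) -> RecordingBundle:
    directory = Path(directory)
    with open(directory / "meta.json") as fh:
        meta = json.load(fh)
    cfg = _config_from_json(meta["config"])
    emg = SignalTrace(
        np.load(directory / "emg.npy"),
        meta["emg"]["sampling_rate"],
        label="EMG",
        unit=meta["emg"].get("unit", ""),
    )
    lfp = SignalTrace(
        np.load(directory / "lfp.npy"),
        meta["lfp"]["sampling_rate"],
        label="LFP",
        unit=meta["lfp"].get("unit", ""),
    )
    hyp = read_hypnogram(directory / "hypnogram.txt")
    spikes = read_spikes(directory / "spikes.tsv")
    truth = read_truth(directory / "truth.tsv")
    return RecordingBundle(hyp=hyp, emg=emg, lfp=lfp, spikes=spikes, truth=truth, config=cfg)


def content_hash(directory) -> str:
    """SHA-256 over the sorted file contents of a bundle directory (logged
    with every analysis run for provenance)."""
    h = hashlib.sha256()
    for p in sorted(Path(directory).rglob("*")):
        if p.is_file():
            h.update(p.name.encode())
            h.update(p.read_bytes())
    return h.hexdigest()
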