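"""Multi-rate PSG record model, event annotations, segmentation, and I/O.

Conventions: intervals are half-open ``[start_s, end_s)`` in seconds from
record start; sample index = floor(t * fs); indexing is 0-based; a slice of
duration d on a channel at rate fs has exactly ``round(d * fs)`` samples.

The reference on-disk dialect is plain text: one CSV per channel plus a JSON
layout describing rates/units, and a ``label,start_s,end_s`` CSV for
annotations. EDF reading is supported through :mod:`mne` when installed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical channel names -> sampling rate in Hz
CANONICAL_RATES = {
    "sao2": 1.0,
    "airflow": 10.0,
    "thoracic": 10.0,
    "abdominal": 10.0,
    "ecg": 125.0,
}

_flagged_rates: set = set()

APNEA = "apnea"
NORMAL = "normal"
LABELS = (APNEA, NORMAL)


@dataclass
class ChannelSeries:
    """A single uniformly sampled channel."""

    name: str
    fs: float
    samples: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError(f"channel {self.name!r}: fs must be positive")
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size == 0:
            raise ValueError(f"channel {self.name!r}: samples must be non-empty")
        canonical = CANONICAL_RATES.get(self.name)
        if canonical is not None and abs(self.fs - canonical) > 1e-9:
            key = (self.name, self.fs)
            if key not in _flagged_rates:  # flag each off-canonical rate once
                _flagged_rates.add(key)
                logger.warning(
                    "channel %r sampled at %g Hz (canonical rate is %g Hz)",
                    self.name, self.fs, canonical,
                )

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    def slice(self, start_s: float, end_s: float) -> "ChannelSeries":
        """Slice ``[start_s, end_s)`` with exactly round(dur*fs) samples."""
        i0 = int(np.floor(start_s * self.fs + 1e-9))
        n = int(round((end_s - start_s) * self.fs))
        if i0 < 0 or i0 + n > self.samples.size:
            raise ValueError(
                f"slice [{start_s}, {end_s}) s outside channel {self.name!r} "
                f"({self.duration_s:.3f} s long)"
            )
        return ChannelSeries(self.name, self.fs, self.samples[i0:i0 + n], self.units)


@dataclass
class PsgRecord:
    """A multi-rate PSG record keyed by canonical channel name."""

    patient_id: str
    channels: dict[str, ChannelSeries]

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("record must carry at least one channel")
        durs = [c.duration_s for c in self.channels.values()]
        tol = max(1.0 / c.fs for c in self.channels.values())
        if max(durs) - min(durs) > tol + 1e-9:
            raise ValueError(
                f"record {self.patient_id!r}: channel durations disagree "
                f"beyond one sample period: {dict((n, c.duration_s) for n, c in self.channels.items())}"
            )

    @property
    def duration_s(self) -> float:
        return min(c.duration_s for c in self.channels.values())

    def require(self, names) -> None:
        missing = [n for n in names if n not in self.channels]
        if missing:
            raise ValueError(
                f"record {self.patient_id!r} is missing channels {missing}; "
                f"present: {sorted(self.channels)}"
            )


@dataclass(frozen=True)
class EventAnnotation:
    """A labelled interval ``[start_s, end_s)``."""

    label: str
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}; expected one of {LABELS}")
        if not self.end_s > self.start_s:
            raise ValueError(f"annotation {self}: end must exceed start")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class Segment:
    """A labelled per-channel time slice of a record."""

    patient_id: str
    label: str
    start_s: float
    end_s: float
    channels: dict[str, ChannelSeries]

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def normalize_annotations(
    annotations: list[EventAnnotation],
    duration_s: float | None = None,
    infer_normal: bool = False,
) -> list[EventAnnotation]:
    """Sort annotations, verify non-overlap, and optionally fill the gaps.

    With ``infer_normal`` the unannotated gaps (including record edges, when
    ``duration_s`` is given) become explicit ``normal`` annotations, for
    files where only apnea events were marked.
    """
    anns = sorted(annotations, key=lambda a: a.start_s)
    for prev, cur in zip(anns, anns[1:]):
        if cur.start_s < prev.end_s - 1e-9:
            raise ValueError(f"overlapping annotations: {prev} and {cur}")
    if not infer_normal:
        return anns
    out: list[EventAnnotation] = []
    cursor = 0.0
    for a in anns:
        if a.start_s > cursor + 1e-9:
            out.append(EventAnnotation(NORMAL, cursor, a.start_s))
        out.append(a)
        cursor = a.end_s
    if duration_s is not None and duration_s > cursor + 1e-9:
        out.append(EventAnnotation(NORMAL, cursor, duration_s))
    return out


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def segment_by_events(
    record: PsgRecord,
    annotations: list[EventAnnotation],
    required_channels=tuple(CANONICAL_RATES),
) -> list[Segment]:
    """One segment per annotation, spanning exactly its interval."""
    record.require(required_channels)
    dur = record.duration_s
    segments = []
    for a in annotations:
        if a.start_s < -1e-9 or a.end_s > dur + 1e-9:
            raise ValueError(f"annotation {a} lies outside the record [0, {dur:.3f}) s")
        chans = {n: record.channels[n].slice(a.start_s, a.end_s) for n in required_channels}
        segments.append(Segment(record.patient_id, a.label, a.start_s, a.end_s, chans))
    return segments


def segment_by_windows(
    record: PsgRecord,
    annotations: list[EventAnnotation],
    window_s: float = 60.0,
    overlap_min_s: float = 10.0,
    required_channels=tuple(CANONICAL_RATES),
) -> list[Segment]:
    """Tile the record with fixed windows; a window is apnea iff its total
    overlap with apnea annotations reaches ``overlap_min_s`` (the clinical
    10 s event minimum by default). The trailing partial window is dropped.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    record.require(required_channels)
    dur = record.duration_s
    if window_s > dur + 1e-9:
        raise ValueError(f"window of {window_s} s exceeds record duration {dur:.3f} s")
    apnea_events = [a for a in annotations if a.label == APNEA]
    k = int(np.floor(dur / window_s + 1e-9))
    segments = []
    for i in range(k):
        w0, w1 = i * window_s, (i + 1) * window_s
        overlap = sum(
            max(0.0, min(w1, a.end_s) - max(w0, a.start_s)) for a in apnea_events
        )
        label = APNEA if overlap >= overlap_min_s else NORMAL
        chans = {n: record.channels[n].slice(w0, w1) for n in required_channels}
        segments.append(Segment(record.patient_id, label, w0, w1, chans))
    return segments


# ---------------------------------------------------------------------------
# I/O: annotations
# ---------------------------------------------------------------------------

def read_annotations(path) -> list[EventAnnotation]:
    """Read a ``label,start_s,end_s`` CSV into annotations."""
    df = pd.read_csv(path)
    expected = {"label", "start_s", "end_s"}
    if not expected.issubset(df.columns):
        raise ValueError(f"annotation file {path} needs columns {sorted(expected)}, "
                         f"found {list(df.columns)}")
    return [
        EventAnnotation(str(r.label), float(r.start_s), float(r.end_s))
        for r in df.itertuples(index=False)
    ]


def write_annotations(annotations: list[EventAnnotation], path) -> None:
    pd.DataFrame(
        [(a.label, a.start_s, a.end_s) for a in annotations],
        columns=["label", "start_s", "end_s"],
    ).to_csv(path, index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# I/O: records
# ---------------------------------------------------------------------------

def write_record(record: PsgRecord, directory) -> None:
    """Write one CSV per channel plus ``layout.json`` (rates and units)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    layout = {"patient_id": record.patient_id, "channels": {}}
    for name, ch in record.channels.items():
        pd.DataFrame({name: ch.samples}).to_csv(
            directory / f"{name}.csv", index=False, float_format="%.12g"
        )
        layout["channels"][name] = {"file": f"{name}.csv", "fs": ch.fs, "units": ch.units}
    (directory / "layout.json").write_text(json.dumps(layout, indent=2))


def _read_record_csv(directory: Path, layout_config: dict | None) -> PsgRecord:
    if layout_config is None:
        layout_path = directory / "layout.json"
        if not layout_path.exists():
            raise ValueError(f"no layout.json in {directory} and no layout_config given")
        layout_config = json.loads(layout_path.read_text())
    channels = {}
    for name, meta in layout_config["channels"].items():
        df = pd.read_csv(directory / meta["file"])
        col = meta.get("column", df.columns[0])
        channels[name] = ChannelSeries(
            name, float(meta["fs"]), df[col].to_numpy(), meta.get("units", "")
        )
    return PsgRecord(layout_config.get("patient_id", directory.name), channels)


def _read_record_edf(path: Path, layout_config: dict | None, patient_id: str | None) -> PsgRecord:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("reading EDF requires the optional 'mne' dependency") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    label_map = (layout_config or {}).get("labels", {n: n for n in raw.ch_names})
    channels = {}
    for file_label, canonical in label_map.items():
        if file_label not in raw.ch_names:
            raise ValueError(
                f"signal label {file_label!r} not in EDF; available: {raw.ch_names}"
            )
        picked = raw.copy().pick([file_label])
        channels[canonical] = ChannelSeries(
            canonical, float(picked.info["sfreq"]), picked.get_data()[0]
        )
    return PsgRecord(patient_id or path.stem, channels)


def read_record(path, layout_config: dict | None = None, patient_id: str | None = None) -> PsgRecord:
    """Read a record from an EDF file or a per-channel CSV directory.

    ``layout_config`` maps file signal labels to canonical channel names
    (EDF) or supplies per-channel file/rate metadata (CSV); for CSV
    directories written by :func:`write_record` it is read from
    ``layout.json``.
    """
    path = Path(path)
    if path.is_file() and path.suffix.lower() == ".edf":
        return _read_record_edf(path, layout_config, patient_id)
    if path.is_dir():
        return _read_record_csv(path, layout_config)
    raise ValueError(f"cannot read record from {path}: expected .edf file or directory")


# ---------------------------------------------------------------------------
# I/O: feature tables
# ---------------------------------------------------------------------------

def write_feature_table(table: pd.DataFrame, path) -> None:
    """Write a feature table (patient_id, label, 66 feature columns)."""
    table.to_csv(path, index=False, float_format="%.12g")


def read_feature_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "label" not in df.columns:
        raise ValueError(f"feature table {path} has no 'label' column")
    return df
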