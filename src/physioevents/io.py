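"""Data model and on-disk formats.

Sessions are exchanged as plain CSV with header ``time_s,eda_us,temp_c,hr_bpm``
(bare ``time,eda,temp,hr`` headers are accepted as aliases). Annotations are
CSV ``time_s,label,note``; detected events are written both as CSV and JSON;
parameter sets round-trip through YAML.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

NOMINAL_FS_HZ = 15.0
CLIP_HALFWIDTH_S = 10.0

_RECORDING_COLUMNS = ("time_s", "eda_us", "temp_c", "hr_bpm")
_COLUMN_ALIASES = {"time": "time_s", "eda": "eda_us", "temp": "temp_c", "hr": "hr_bpm"}
_EVENT_COLUMNS = ("time_s", "score", "dominant_modality", "clip_start_s", "clip_end_s")
MODALITIES = ("eda", "temp", "hr")
ANNOTATION_LABELS = ("significant", "not_significant")


class FormatError(ValueError):
    """A file does not conform to the expected dialect."""


class ValidationError(ValueError):
    """A value violates a data-model invariant."""


@dataclass
class PhysioRecording:
    """Raw three-channel autonomic session sampled at a nominal 15 Hz.

    Attributes
    ----------
    session_id : str
        Free-form identifier, usually derived from the file name.
    t : ndarray
        Strictly increasing time axis in seconds from session start.
    eda : ndarray
        Electrodermal activity (skin conductance) in microsiemens.
    temp : ndarray
        Peripheral skin temperature in degrees Celsius.
    hr : ndarray
        Heart rate in beats per minute.
    fs : float
        Sampling frequency in Hz, inferred from the time axis on read.
    """

    session_id: str
    t: np.ndarray
    eda: np.ndarray
    temp: np.ndarray
    hr: np.ndarray
    fs: float = NOMINAL_FS_HZ

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.eda = np.asarray(self.eda, dtype=float)
        self.temp = np.asarray(self.temp, dtype=float)
        self.hr = np.asarray(self.hr, dtype=float)
        n = self.t.size
        for name in ("eda", "temp", "hr"):
            if getattr(self, name).size != n:
                raise ValidationError(f"channel {name!r} length != time axis length")
        if n >= 2 and not np.all(np.diff(self.t) > 0):
            raise ValidationError("time axis must be strictly increasing")
        if not self.fs > 0:
            raise ValidationError("sampling frequency must be positive")

    @property
    def span(self) -> tuple[float, float]:
        return float(self.t[0]), float(self.t[-1])

    def __len__(self) -> int:
        return int(self.t.size)


@dataclass(frozen=True)
class Annotation:
    time_s: float
    label: str
    note: str = ""

    def __post_init__(self) -> None:
        if self.label not in ANNOTATION_LABELS:
            raise ValidationError(f"label must be one of {ANNOTATION_LABELS}")


@dataclass
class AnnotationSet:
    """Timestamped subjective judgements of salient / non-salient moments."""

    annotations: list[Annotation] = field(default_factory=list)

    def __iter__(self):
        return iter(self.annotations)

    def __len__(self) -> int:
        return len(self.annotations)

    @property
    def significant_times(self) -> np.ndarray:
        return np.array(
            [a.time_s for a in self.annotations if a.label == "significant"], dtype=float
        )

    def validate_span(self, span: tuple[float, float]) -> None:
        lo, hi = span
        for a in self.annotations:
            if not (lo <= a.time_s <= hi):
                raise ValidationError(
                    f"annotation at {a.time_s} s outside recording span [{lo}, {hi}]"
                )


@dataclass(frozen=True)
class Event:
    """A detected salient moment.

    ``score`` is the dimensionless weighted sum S of the three feature
    magnitudes; the clip window is the ±10 s segment of synchronized video
    that would be shown back to the dyad, truncated at session edges.
    """

    time_s: float
    score: float
    dominant_modality: str
    clip_start_s: float
    clip_end_s: float

    def __post_init__(self) -> None:
        if self.dominant_modality not in MODALITIES:
            raise ValidationError(f"dominant_modality must be one of {MODALITIES}")
        if not (self.clip_start_s <= self.time_s <= self.clip_end_s):
            raise ValidationError("event time must lie inside its clip window")
        if self.clip_end_s - self.clip_start_s > 2 * CLIP_HALFWIDTH_S + 1e-9:
            raise ValidationError("clip window longer than 20 s")


@dataclass
class DetectorParams:
    """Tunable detection thresholds and modality weights.

    Defaults are the canonical untailored settings: an electrodermal reaction
    is a rise of at least 0.05 µS within 10 s, heart-rate peaks must have a
    prominence of at least 10 bpm, and a temperature trend is a max-min
    range of at least 0.01 °C within 10 s. Weights a, b, c scale the EDA,
    temperature and heart-rate feature magnitudes in the combined score and
    start at 1. Heart-rate prominence is measured against the local pattern
    within ``prominence_wlen_s`` of each extremum.
    """

    t_edr_s: float = 10.0
    a_edr_us: float = 0.05
    min_peak_prominence_bpm: float = 10.0
    prominence_wlen_s: float = 60.0
    t_temp_s: float = 10.0
    dt_min_c: float = 0.01
    a: float = 1.0
    b: float = 1.0
    c: float = 1.0
    max_events: int = 5
    min_sep_s: float = 20.0
    clip_halfwidth_s: float = CLIP_HALFWIDTH_S

    def __post_init__(self) -> None:
        if self.t_edr_s <= 0 or self.t_temp_s <= 0:
            raise ValidationError("window lengths must be positive")
        if min(self.a_edr_us, self.min_peak_prominence_bpm, self.dt_min_c) < 0:
            raise ValidationError("thresholds must be non-negative")
        if min(self.a, self.b, self.c) < 0:
            raise ValidationError("weights must be non-negative")
        if self.max_events < 0 or int(self.max_events) != self.max_events:
            raise ValidationError("max_events must be a non-negative integer")

    def replace(self, **kwargs) -> "DetectorParams":
        return dataclasses.replace(self, **kwargs)


# ---------------------------------------------------------------------------
# Recording I/O


def read_recording(path: str | Path, session_id: str | None = None) -> PhysioRecording:
    """Read a session CSV and infer the sampling frequency.

    The frequency is taken as 1/median(Δt); a warning is emitted when it
    deviates from the nominal 15 Hz by more than 10%.
    """
    path = Path(path)
    df = pd.read_csv(path)
    df = df.rename(columns=_COLUMN_ALIASES)
    missing = [c for c in _RECORDING_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    t = df["time_s"].to_numpy(dtype=float)
    if t.size >= 2:
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValidationError(f"{path}: time axis not strictly increasing")
        fs = 1.0 / float(np.median(dt))
    else:
        fs = NOMINAL_FS_HZ
    if abs(fs - NOMINAL_FS_HZ) / NOMINAL_FS_HZ > 0.10:
        warnings.warn(
            f"{path}: inferred sampling frequency {fs:.3g} Hz deviates from "
            f"nominal {NOMINAL_FS_HZ:g} Hz by more than 10%",
            stacklevel=2,
        )
    return PhysioRecording(
        session_id=session_id or path.stem,
        t=t,
        eda=df["eda_us"].to_numpy(dtype=float),
        temp=df["temp_c"].to_numpy(dtype=float),
        hr=df["hr_bpm"].to_numpy(dtype=float),
        fs=fs,
    )


def write_recording(rec: PhysioRecording, path: str | Path) -> None:
    df = pd.DataFrame(
        {"time_s": rec.t, "eda_us": rec.eda, "temp_c": rec.temp, "hr_bpm": rec.hr}
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Annotation I/O


def read_annotations(path: str | Path) -> AnnotationSet:
    df = pd.read_csv(path, keep_default_na=False)
    missing = [c for c in ("time_s", "label") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    notes = df["note"] if "note" in df.columns else [""] * len(df)
    return AnnotationSet(
        [
            Annotation(float(t), str(lab), str(note))
            for t, lab, note in zip(df["time_s"], df["label"], notes)
        ]
    )


def write_annotations(ann: AnnotationSet, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "time_s": [a.time_s for a in ann],
            "label": [a.label for a in ann],
            "note": [a.note for a in ann],
        },
        columns=["time_s", "label", "note"],
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Event I/O


def write_events(events: Sequence[Event], path: str | Path) -> None:
    """Write detected events as CSV; a sibling ``.json`` file is also written."""
    path = Path(path)
    rows = [
        {
            "time_s": e.time_s,
            "score": e.score,
            "dominant_modality": e.dominant_modality,
            "clip_start_s": e.clip_start_s,
            "clip_end_s": e.clip_end_s,
        }
        for e in events
    ]
    pd.DataFrame(rows, columns=_EVENT_COLUMNS).to_csv(path, index=False)
    path.with_suffix(".json").write_text(json.dumps(rows, indent=2) + "\n")


def read_events(path: str | Path) -> list[Event]:
    path = Path(path)
    if path.suffix == ".json":
        rows = json.loads(path.read_text())
    else:
        rows = pd.read_csv(path).to_dict("records")
    return [
        Event(
            time_s=float(r["time_s"]),
            score=float(r["score"]),
            dominant_modality=str(r["dominant_modality"]),
            clip_start_s=float(r["clip_start_s"]),
            clip_end_s=float(r["clip_end_s"]),
        )
        for r in rows
    ]


# ---------------------------------------------------------------------------
# Parameter I/O


def write_params(params: DetectorParams, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(dataclasses.asdict(params), sort_keys=False))


def read_params(path: str | Path) -> DetectorParams:
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise FormatError(f"{path}: expected a mapping of parameter fields")
    known = {f.name for f in dataclasses.fields(DetectorParams)}
    unknown = set(data) - known
    if unknown:
        raise FormatError(f"{path}: unknown parameter field(s) {sorted(unknown)}")
    return DetectorParams(**data)


# ---------------------------------------------------------------------------
# Clip geometry


def clip_window(
    time_s: float,
    recording_span: tuple[float, float],
    halfwidth_s: float = CLIP_HALFWIDTH_S,
) -> tuple[float, float]:
    """Video clip window around an event: ±halfwidth, truncated to the span."""
    lo, hi = recording_span
    if not (lo <= time_s <= hi):
        raise ValidationError(f"event time {time_s} s outside span [{lo}, {hi}]")
    return max(lo, time_s - halfwidth_s), min(hi, time_s + halfwidth_s)
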