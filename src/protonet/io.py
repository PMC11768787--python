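"""File formats, validation and window labelling.

Recordings are long CSVs with header ``time_s,acc_x,acc_y,acc_z`` (seconds /
g units); annotations are CSVs with ``start_s,end_s,label,sub_class,prototype``
using half-open intervals ``[start, end)`` in seconds from recording start.

Sub-class vocabulary: seven tremor phenotypes ``T1..T7`` (wrist/finger
flexion-extension, elbow flexion-extension, pronation-supination — each with
the arm supported or free — plus tremor during gait) and seven non-tremor
activities ``N1..N7`` (gait, postural transitions, running/exercising,
driving bike/car, "suspicious" periodic upper-limb activity, other upper-limb
activity, no upper-limb activity).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

TREMOR_SUBCLASSES = tuple(f"T{i}" for i in range(1, 8))
NONTREMOR_SUBCLASSES = tuple(f"N{i}" for i in range(1, 8))
VALID_SUBCLASSES = TREMOR_SUBCLASSES + NONTREMOR_SUBCLASSES
LABELS = ("tremor", "non_tremor")

#: time-uniformity tolerance in seconds
_DT_TOL = 1e-6


class FormatError(ValueError):
    """Raised when a file does not match the expected schema."""


class ValidationError(ValueError):
    """Raised when parsed content violates a domain invariant."""


@dataclass
class RawRecording:
    """A tri-axial wrist accelerometer stream for one subject/side.

    Attributes
    ----------
    subject_id : str
    side : str
        ``"left"`` or ``"right"``.
    rate_hz : float
        Sampling rate; 200 Hz for raw device output, 50 Hz after decimation.
    t : ndarray, shape (n,)
        Sample times in seconds, strictly increasing, uniform to 1e-6 s.
    acc : ndarray, shape (n, 3)
        Acceleration in g, axes (x, y, z).
    """

    subject_id: str
    side: str
    rate_hz: float
    t: np.ndarray
    acc: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.acc = np.asarray(self.acc, dtype=float)
        if self.acc.ndim != 2 or self.acc.shape[1] != 3:
            raise ValidationError("acc must have shape (n, 3)")
        if len(self.t) != len(self.acc):
            raise ValidationError("t and acc lengths differ")
        if self.side not in ("left", "right"):
            raise ValidationError(f"side must be left/right, got {self.side!r}")
        if len(self.t) > 1:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                raise ValidationError("sample times must be strictly increasing")
            if np.any(np.abs(dt - 1.0 / self.rate_hz) > _DT_TOL):
                raise ValidationError(
                    f"non-uniform sampling: expected dt={1.0 / self.rate_hz:g} s"
                )

    @property
    def duration_s(self) -> float:
        return len(self.t) / self.rate_hz

    def with_acc(self, acc: np.ndarray) -> "RawRecording":
        return replace(self, acc=np.asarray(acc, dtype=float))


@dataclass(frozen=True)
class Interval:
    """Half-open annotated interval ``[start, end)`` in seconds."""

    start: float
    end: float
    label: str
    sub_class: str = "none"
    prototype: bool = False

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValidationError(f"interval start {self.start} >= end {self.end}")
        if self.label not in LABELS:
            raise ValidationError(f"label must be one of {LABELS}, got {self.label!r}")
        if self.sub_class != "none":
            if self.sub_class not in VALID_SUBCLASSES:
                raise ValidationError(
                    f"unknown sub-class {self.sub_class!r}; "
                    f"valid tokens: {', '.join(VALID_SUBCLASSES)}"
                )
            if self.label == "tremor" and self.sub_class not in TREMOR_SUBCLASSES:
                raise ValidationError("tremor intervals take T1..T7 sub-classes")
            if self.label == "non_tremor" and self.sub_class not in NONTREMOR_SUBCLASSES:
                raise ValidationError("non-tremor intervals take N1..N7 sub-classes")
        if self.prototype and self.sub_class == "none":
            raise ValidationError("prototype intervals must carry a sub-class")


@dataclass
class AnnotationTrack:
    """Interval labels aligned to one subject's recording."""

    subject_id: str
    intervals: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intervals = merge_intervals(self.intervals)

    def of_label(self, label: str) -> list[Interval]:
        return [iv for iv in self.intervals if iv.label == label]

    def total_duration(self, label: str) -> float:
        return float(sum(iv.end - iv.start for iv in self.of_label(label)))


def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Sort intervals and merge overlapping/abutting ones with identical
    (label, sub_class, prototype)."""
    # total order: co-located intervals of different kinds sort stably too
    ordered = sorted(
        intervals,
        key=lambda iv: (iv.start, iv.end, iv.label, iv.sub_class, iv.prototype),
    )
    merged: list[Interval] = []
    for iv in ordered:
        if merged:
            last = merged[-1]
            same = (iv.label, iv.sub_class, iv.prototype) == (
                last.label,
                last.sub_class,
                last.prototype,
            )
            if same and iv.start <= last.end:
                merged[-1] = replace(last, end=max(last.end, iv.end))
                continue
        merged.append(iv)
    return merged


# ---------------------------------------------------------------------------
# Recording I/O

_REC_COLUMNS = {"time": "time_s", "x": "acc_x", "y": "acc_y", "z": "acc_z"}


def read_recording(
    path: str | Path,
    schema: dict[str, str] | None = None,
    subject_id: str | None = None,
    side: str = "right",
) -> RawRecording:
    """Read a recording CSV.

    ``schema`` maps the logical columns ``time, x, y, z`` to CSV column names
    (default ``time_s, acc_x, acc_y, acc_z``). The sampling rate is inferred
    from the median time step and validated for uniformity.
    """
    cols = dict(_REC_COLUMNS)
    if schema:
        cols.update(schema)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in cols.values() if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    t = df[cols["time"]].to_numpy(dtype=float)
    acc = df[[cols["x"], cols["y"], cols["z"]]].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValidationError(f"{path}: need at least 2 samples to infer rate")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValidationError(f"{path}: non-monotone or duplicated timestamps")
    rate = 1.0 / float(np.median(dt))
    rate = round(rate, 6)
    sid = subject_id if subject_id is not None else Path(path).stem
    return RawRecording(subject_id=sid, side=side, rate_hz=rate, t=t, acc=acc)


def write_recording(rec: RawRecording, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "time_s": rec.t,
            "acc_x": rec.acc[:, 0],
            "acc_y": rec.acc[:, 1],
            "acc_z": rec.acc[:, 2],
        }
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Annotation I/O


def read_annotations(path: str | Path, subject_id: str | None = None) -> AnnotationTrack:
    """Read an annotation CSV (``start_s,end_s,label[,sub_class,prototype]``).

    Overlapping intervals with identical (label, sub-class, prototype) are
    merged; domain invariants are validated per row.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    required = ["start_s", "end_s", "label"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    intervals = []
    for row in df.itertuples(index=False):
        sub = getattr(row, "sub_class", "none")
        if isinstance(sub, float) and np.isnan(sub):
            sub = "none"
        proto = bool(getattr(row, "prototype", False))
        intervals.append(
            Interval(
                start=float(row.start_s),
                end=float(row.end_s),
                label=str(row.label),
                sub_class=str(sub),
                prototype=proto,
            )
        )
    sid = subject_id if subject_id is not None else Path(path).stem
    return AnnotationTrack(subject_id=sid, intervals=intervals)


def write_annotations(track: AnnotationTrack, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "start_s": [iv.start for iv in track.intervals],
            "end_s": [iv.end for iv in track.intervals],
            "label": [iv.label for iv in track.intervals],
            "sub_class": [iv.sub_class for iv in track.intervals],
            "prototype": [iv.prototype for iv in track.intervals],
        }
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Window labelling

#: a window takes a class label when that class covers >50% of its span
MAJORITY_FRACTION = 0.5
#: sub-class / prototype tags require a single sub-class covering >=90%
PURITY_FRACTION = 0.9


def label_windows(windows: pd.DataFrame, track: AnnotationTrack) -> pd.DataFrame:
    """Assign (label, sub_class, prototype, excluded) to each 2-s window.

    ``windows`` needs columns ``subject_id, start, end``. A window is labelled
    with the class covering the majority (>50%) of its span; a sub-class (and
    the prototype flag) is assigned only when a single sub-class covers at
    least 90% of the span. Windows whose span has no majority class (including
    unannotated spans) get ``excluded=True``.

    Invariant to annotation order and to splitting intervals into abutting
    pieces (coverage is additive).
    """
    if len(windows) and "subject_id" in windows.columns:
        subjects = set(windows["subject_id"].unique())
        if subjects - {track.subject_id}:
            raise ValidationError(
                f"windows belong to {subjects}, track to {track.subject_id!r}"
            )
    starts = windows["start"].to_numpy(dtype=float)
    ends = windows["end"].to_numpy(dtype=float)
    n = len(starts)
    label_cov = {lab: np.zeros(n) for lab in LABELS}
    sub_cov: dict[str, np.ndarray] = {}
    proto_cov: dict[str, np.ndarray] = {}
    for iv in track.intervals:
        ov = np.clip(np.minimum(ends, iv.end) - np.maximum(starts, iv.start), 0.0, None)
        label_cov[iv.label] += ov
        if iv.sub_class != "none":
            sub_cov.setdefault(iv.sub_class, np.zeros(n))
            sub_cov[iv.sub_class] += ov
            if iv.prototype:
                proto_cov.setdefault(iv.sub_class, np.zeros(n))
                proto_cov[iv.sub_class] += ov

    span = ends - starts
    out = windows.copy()
    labels = np.full(n, "none", dtype=object)
    subs = np.full(n, "none", dtype=object)
    protos = np.zeros(n, dtype=bool)
    excluded = np.ones(n, dtype=bool)
    for lab in LABELS:
        hit = label_cov[lab] > MAJORITY_FRACTION * span
        labels[hit] = lab
        excluded[hit] = False
    for sub, cov in sub_cov.items():
        pure = cov >= PURITY_FRACTION * span
        # a sub-class tag must agree with the window's class label
        cls = "tremor" if sub in TREMOR_SUBCLASSES else "non_tremor"
        pure &= labels == cls
        subs[pure] = sub
        if sub in proto_cov:
            protos[pure & (proto_cov[sub] >= PURITY_FRACTION * span)] = True
    out["label"] = labels
    out["sub_class"] = subs
    out["prototype"] = protos
    out["excluded"] = excluded
    return out


# ---------------------------------------------------------------------------
# Reports


def write_report(report: dict, path: str | Path) -> None:
    """Serialize an evaluation report to JSON (+ per-fold CSV alongside).

    Keys are written in sorted order so reports are diff-able. If the report
    carries a ``folds`` list of records, a sibling ``<stem>_folds.csv`` is
    emitted.
    """
    path = Path(path)
    try:
        with open(path, "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True, default=_jsonify)
    except OSError as exc:  # pragma: no cover - depends on filesystem
        raise IOError(f"cannot write report to {path}: {exc}") from exc
    folds = report.get("folds")
    if folds:
        pd.DataFrame(folds).to_csv(path.with_name(path.stem + "_folds.csv"), index=False)


def read_report(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
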