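"""Data model and I/O for force recordings, annotations and task segments.

A recording is the raw two-prong (left/right jaw) force time series for one
surgical case.  Annotations mark episodes of force application with a task
label and the operating surgeon's identity and experience level.  Segmenting
a recording by its annotations yields :class:`ForceSegment` objects — the
atomic unit every downstream stage (preprocessing, feature engineering,
modelling) operates on.

On-disk formats (all plain text, UTF-8, '.' decimal separator):

* recordings: CSV with columns ``time_s,left_force_n,right_force_n``
* annotations: CSV with columns
  ``start_s,end_s,task,surgeon_id,experience,pgy_band,event_flags``
  (``event_flags`` is a ';'-separated token list, may be empty)
* segment tables: long CSV ``segment_id,time_s,left_force_n,right_force_n``
  plus a JSON sidecar of per-segment metadata
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .catalog import EVENT_FLAGS, EXPERIENCE_LEVELS, TASKS
from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

RECORDING_COLUMNS = ("time_s", "left_force_n", "right_force_n")
ANNOTATION_COLUMNS = (
    "start_s",
    "end_s",
    "task",
    "surgeon_id",
    "experience",
    "pgy_band",
    "event_flags",
)


@dataclass(frozen=True)
class ForceRecording:
    """Raw two-prong force time series for one case.

    ``time`` is 0-based seconds from recording start and must be strictly
    increasing; ``sampling_rate`` (samples/s) must agree with the median time
    step to within 1%.
    """

    case_id: str
    sampling_rate: float
    time: np.ndarray
    left_force: np.ndarray
    right_force: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        time = np.asarray(self.time, dtype=float)
        left = np.asarray(self.left_force, dtype=float)
        right = np.asarray(self.right_force, dtype=float)
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "left_force", left)
        object.__setattr__(self, "right_force", right)
        if not (len(time) == len(left) == len(right)):
            raise ValidationError("time/left/right arrays must have equal length")
        if len(time) < 2:
            raise ValidationError("a recording needs at least 2 samples")
        if not np.all(np.diff(time) > 0):
            raise ValidationError("time must be strictly increasing")
        for name, arr in (("time", time), ("left_force", left), ("right_force", right)):
            if not np.all(np.isfinite(arr)):
                raise ValidationError(f"{name} contains non-finite values")
        if self.sampling_rate <= 0:
            raise ValidationError("sampling_rate must be positive")
        median_dt = float(np.median(np.diff(time)))
        if abs(median_dt * self.sampling_rate - 1.0) > 0.01:
            raise ValidationError(
                f"median time step {median_dt:.6g}s inconsistent with "
                f"sampling_rate {self.sampling_rate:g} Hz (>1% off)"
            )

    @property
    def n_samples(self) -> int:
        return len(self.time)


@dataclass(frozen=True)
class SegmentAnnotation:
    """One annotated episode of force application."""

    start: float
    end: float
    task: str
    surgeon_id: str
    experience: str
    pgy_band: str | None = None
    event_flags: frozenset = frozenset()

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValidationError(f"annotation start {self.start} must precede end {self.end}")
        if self.task not in TASKS:
            raise ValidationError(f"unknown task label {self.task!r}; expected one of {TASKS}")
        if self.experience not in EXPERIENCE_LEVELS:
            raise ValidationError(
                f"unknown experience {self.experience!r}; expected one of {EXPERIENCE_LEVELS}"
            )
        flags = frozenset(self.event_flags)
        if not flags <= EVENT_FLAGS:
            raise ValidationError(f"unknown event flags {sorted(flags - EVENT_FLAGS)}")
        object.__setattr__(self, "event_flags", flags)


@dataclass(frozen=True)
class ForceSegment:
    """One task episode of force application cut from a recording."""

    segment_id: str
    case_id: str
    sampling_rate: float
    left_force: np.ndarray
    right_force: np.ndarray
    task: str
    surgeon_id: str
    experience: str
    pgy_band: str | None = None
    event_flags: frozenset = frozenset()
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        left = np.asarray(self.left_force, dtype=float)
        right = np.asarray(self.right_force, dtype=float)
        object.__setattr__(self, "left_force", left)
        object.__setattr__(self, "right_force", right)
        object.__setattr__(self, "event_flags", frozenset(self.event_flags))
        if len(left) == 0 or len(left) != len(right):
            raise ValidationError("segment force arrays must be non-empty and equal-length")
        if not (np.all(np.isfinite(left)) and np.all(np.isfinite(right))):
            raise ValidationError("segment forces contain non-finite values")
        if self.sampling_rate <= 0:
            raise ValidationError("sampling_rate must be positive")
        if self.task not in TASKS:
            raise ValidationError(f"unknown task label {self.task!r}")
        if self.experience not in EXPERIENCE_LEVELS:
            raise ValidationError(f"unknown experience {self.experience!r}")

    @property
    def n_samples(self) -> int:
        return len(self.left_force)

    @property
    def duration(self) -> float:
        """Segment duration in seconds (n_samples / sampling_rate)."""
        return self.n_samples / self.sampling_rate

    def channel(self, name: str) -> np.ndarray:
        """Return one analysis channel: 'left', 'right' or 'max' (elementwise)."""
        if name == "left":
            return self.left_force
        if name == "right":
            return self.right_force
        if name == "max":
            return np.maximum(self.left_force, self.right_force)
        raise ValidationError(f"unknown channel {name!r}; expected left/right/max")

    def with_forces(self, left: np.ndarray, right: np.ndarray, note: str | None = None) -> "ForceSegment":
        meta = dict(self.metadata)
        if note:
            meta.setdefault("processing", [])
            meta["processing"] = list(meta["processing"]) + [note]
        return replace(self, left_force=left, right_force=right, metadata=meta)


@dataclass
class SegmentTable:
    """Ordered collection of segments with unique ids plus provenance text."""

    segments: list[ForceSegment]
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [s.segment_id for s in self.segments]
        if len(ids) != len(set(ids)):
            raise ValidationError("segment_ids must be unique")

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self) -> Iterator[ForceSegment]:
        return iter(self.segments)

    def __getitem__(self, i: int) -> ForceSegment:
        return self.segments[i]

    def filter(self, predicate) -> "SegmentTable":
        return SegmentTable(
            [s for s in self.segments if predicate(s)],
            provenance=self.provenance + " | filtered",
        )

    def metadata_frame(self) -> pd.DataFrame:
        """Per-segment metadata as a DataFrame (one row per segment)."""
        rows = [
            {
                "segment_id": s.segment_id,
                "case_id": s.case_id,
                "task": s.task,
                "surgeon_id": s.surgeon_id,
                "experience": s.experience,
                "pgy_band": s.pgy_band,
                "duration": s.duration,
                "n_samples": s.n_samples,
            }
            for s in self.segments
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "segment_id",
                "case_id",
                "task",
                "surgeon_id",
                "experience",
                "pgy_band",
                "duration",
                "n_samples",
            ],
        )


# ---------------------------------------------------------------------------
# Recording I/O


def read_recording(
    path: str | Path,
    sampling_rate_override: float | None = None,
    case_id: str | None = None,
) -> ForceRecording:
    """Read a recording CSV (``time_s,left_force_n,right_force_n``).

    The sampling rate is inferred from the median time step unless
    ``sampling_rate_override`` is given.
    """
    path = Path(path)
    try:
        # round_trip parsing keeps write->read bitwise exact
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"cannot parse recording CSV {path}: {exc}") from exc
    missing = [c for c in RECORDING_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"recording {path} is missing columns {missing}")
    time = df["time_s"].to_numpy(dtype=float)
    if len(time) >= 2 and not np.all(np.diff(time) > 0):
        raise ValidationError(f"recording {path}: time_s is not strictly increasing")
    if sampling_rate_override is not None:
        fs = float(sampling_rate_override)
    else:
        if len(time) < 2:
            raise ValidationError(f"recording {path}: need >= 2 samples to infer sampling rate")
        fs = 1.0 / float(np.median(np.diff(time)))
    return ForceRecording(
        case_id=case_id or path.stem,
        sampling_rate=fs,
        time=time,
        left_force=df["left_force_n"].to_numpy(dtype=float),
        right_force=df["right_force_n"].to_numpy(dtype=float),
    )


def write_recording(rec: ForceRecording, path: str | Path) -> None:
    """Write a recording to the documented CSV format."""
    df = pd.DataFrame(
        {
            "time_s": rec.time,
            "left_force_n": rec.left_force,
            "right_force_n": rec.right_force,
        }
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Annotations


def read_annotations(path: str | Path) -> list[SegmentAnnotation]:
    """Read an annotation CSV; rejects unknown task/experience labels."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in ANNOTATION_COLUMNS[:5] if c not in df.columns]
    if missing:
        raise FormatError(f"annotations {path} missing columns {missing}")
    out = []
    for _, row in df.iterrows():
        flags = frozenset(t for t in str(row.get("event_flags", "")).split(";") if t)
        out.append(
            SegmentAnnotation(
                start=float(row["start_s"]),
                end=float(row["end_s"]),
                task=row["task"],
                surgeon_id=row["surgeon_id"],
                experience=row["experience"],
                pgy_band=row.get("pgy_band") or None,
                event_flags=flags,
            )
        )
    return out


def write_annotations(annotations: Sequence[SegmentAnnotation], path: str | Path) -> None:
    rows = [
        {
            "start_s": a.start,
            "end_s": a.end,
            "task": a.task,
            "surgeon_id": a.surgeon_id,
            "experience": a.experience,
            "pgy_band": a.pgy_band or "",
            "event_flags": ";".join(sorted(a.event_flags)),
        }
        for a in annotations
    ]
    pd.DataFrame(rows, columns=list(ANNOTATION_COLUMNS)).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Segmentation


def segment_recording(
    rec: ForceRecording,
    annotations: Iterable[SegmentAnnotation],
    clock_offset: float = 0.0,
) -> SegmentTable:
    """Cut a recording into segments at the annotated intervals.

    Each annotation selects samples in the half-open window
    ``[start + clock_offset, end + clock_offset)`` so tiling annotations
    partition the recording without double-assigning boundary samples.
    ``clock_offset`` absorbs the annotation-vs-force clock misalignment.
    Annotations with fewer than 2 samples inside the recording are dropped
    with a logged warning.
    """
    anns = sorted(annotations, key=lambda a: a.start)
    for prev, cur in zip(anns, anns[1:]):
        if cur.start < prev.end:
            raise ValidationError(
                f"annotations overlap: [{prev.start}, {prev.end}) and [{cur.start}, {cur.end})"
            )
    segments = []
    for k, ann in enumerate(anns):
        lo = np.searchsorted(rec.time, ann.start + clock_offset, side="left")
        hi = np.searchsorted(rec.time, ann.end + clock_offset, side="left")
        if hi - lo < 2:
            logger.warning(
                "annotation [%s, %s) task=%s yields %d samples in case %s; dropped",
                ann.start,
                ann.end,
                ann.task,
                hi - lo,
                rec.case_id,
            )
            continue
        segments.append(
            ForceSegment(
                segment_id=f"{rec.case_id}-{k:04d}",
                case_id=rec.case_id,
                sampling_rate=rec.sampling_rate,
                left_force=rec.left_force[lo:hi].copy(),
                right_force=rec.right_force[lo:hi].copy(),
                task=ann.task,
                surgeon_id=ann.surgeon_id,
                experience=ann.experience,
                pgy_band=ann.pgy_band,
                event_flags=ann.event_flags,
            )
        )
    return SegmentTable(segments, provenance=f"segmented case {rec.case_id} (offset {clock_offset}s)")


# ---------------------------------------------------------------------------
# Segment table I/O (long CSV + JSON sidecar)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def write_segments(table: SegmentTable, path: str | Path) -> None:
    """Write a segment table as long CSV plus a JSON metadata sidecar."""
    path = Path(path)
    frames = []
    meta = []
    for s in table:
        frames.append(
            pd.DataFrame(
                {
                    "segment_id": s.segment_id,
                    "time_s": np.arange(s.n_samples) / s.sampling_rate,
                    "left_force_n": s.left_force,
                    "right_force_n": s.right_force,
                }
            )
        )
        meta.append(
            {
                "segment_id": s.segment_id,
                "case_id": s.case_id,
                "sampling_rate": s.sampling_rate,
                "task": s.task,
                "surgeon_id": s.surgeon_id,
                "experience": s.experience,
                "pgy_band": s.pgy_band,
                "event_flags": sorted(s.event_flags),
                "metadata": s.metadata,
            }
        )
    if frames:
        long_df = pd.concat(frames, ignore_index=True)
    else:
        long_df = pd.DataFrame(columns=["segment_id", "time_s", "left_force_n", "right_force_n"])
    long_df.to_csv(path, index=False)
    sidecar = {"provenance": table.provenance, "segments": meta}
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))


def read_segments(path: str | Path) -> SegmentTable:
    """Read a segment table written by :func:`write_segments`."""
    path = Path(path)
    sidecar_file = _sidecar_path(path)
    if not sidecar_file.exists():
        raise FormatError(f"missing metadata sidecar {sidecar_file}")
    sidecar = json.loads(sidecar_file.read_text())
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in ("segment_id", "time_s", "left_force_n", "right_force_n") if c not in df.columns]
    if missing:
        raise FormatError(f"segment CSV {path} missing columns {missing}")
    by_id = {sid: g for sid, g in df.groupby("segment_id", sort=False)}
    meta_ids = {m["segment_id"] for m in sidecar["segments"]}
    orphan = set(by_id) - meta_ids
    if orphan:
        raise FormatError(f"segments present in CSV but absent from sidecar: {sorted(orphan)}")
    segments = []
    for m in sidecar["segments"]:
        g = by_id.get(m["segment_id"])
        if g is None:
            raise FormatError(f"segment {m['segment_id']} in sidecar but not in CSV")
        segments.append(
            ForceSegment(
                segment_id=m["segment_id"],
                case_id=m["case_id"],
                sampling_rate=m["sampling_rate"],
                left_force=g["left_force_n"].to_numpy(dtype=float),
                right_force=g["right_force_n"].to_numpy(dtype=float),
                task=m["task"],
                surgeon_id=m["surgeon_id"],
                experience=m["experience"],
                pgy_band=m.get("pgy_band"),
                event_flags=frozenset(m.get("event_flags", [])),
                metadata=m.get("metadata", {}),
            )
        )
    return SegmentTable(segments, provenance=sidecar.get("provenance", ""))
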