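"""Segment preprocessing: low-pass smoothing and expert-percentile outlier removal.

Smoothing uses a 4th-order Butterworth low-pass filter, by default applied
forward-backward (zero-phase) so timing-sensitive features are not biased by
phase lag; a causal single-pass mode is available for streaming parity.

Outlier screening assumes that an experienced surgeon commits < 1% of the
extreme episodes: per-segment maximum force, minimum force and completion
time are summarized over all Expert segments, and any segment whose
statistic leaves the expert [1st, 99th] percentile band is flagged.
Flagging and removal are separate pure steps so the decision is auditable.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .errors import FittingError, ParameterError
from .segment_io import ForceSegment, SegmentTable

DEFAULT_ANALYSIS_CHANNEL = "right"


@dataclass(frozen=True)
class FilterSpec:
    """Low-pass Butterworth filter parameters.

    ``cutoff`` is in absolute Hz and must stay below the Nyquist frequency of
    the segment it is applied to.  ``zero_phase`` runs the filter forward and
    backward (squared magnitude response, no phase lag); ``causal`` is a
    single forward pass.
    """

    order: int = 4
    cutoff: float = 0.1
    mode: str = "zero_phase"

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ParameterError("filter order must be >= 1")
        if self.cutoff <= 0:
            raise ParameterError("cutoff must be positive (Hz)")
        if self.mode not in ("zero_phase", "causal"):
            raise ParameterError(f"unknown filter mode {self.mode!r}")


def _sos(spec: FilterSpec, fs: float):
    nyquist = fs / 2.0
    if spec.cutoff >= nyquist:
        raise ParameterError(
            f"cutoff {spec.cutoff:g} Hz must be below the Nyquist frequency "
            f"{nyquist:g} Hz at sampling rate {fs:g} Hz"
        )
    return signal.butter(spec.order, spec.cutoff, btype="low", fs=fs, output="sos")


def min_segment_length(spec: FilterSpec) -> int:
    """Smallest segment length the zero-phase filter can edge-pad."""
    # sosfiltfilt pads with 3 * (2 * n_sections + 1) samples on each side
    n_sections = (spec.order + 1) // 2
    return 3 * (2 * n_sections + 1) + 1


def smooth_segment(seg: ForceSegment, spec: FilterSpec = FilterSpec()) -> ForceSegment:
    """Low-pass both prongs of a segment; output length equals input length."""
    sos = _sos(spec, seg.sampling_rate)
    if spec.mode == "zero_phase":
        min_len = min_segment_length(spec)
        if seg.n_samples < min_len:
            raise ParameterError(
                f"segment {seg.segment_id} has {seg.n_samples} samples; zero-phase "
                f"filtering with order {spec.order} needs at least {min_len}"
            )
        left = signal.sosfiltfilt(sos, seg.left_force)
        right = signal.sosfiltfilt(sos, seg.right_force)
    else:
        zi = signal.sosfilt_zi(sos)
        left, _ = signal.sosfilt(sos, seg.left_force, zi=zi * seg.left_force[0])
        right, _ = signal.sosfilt(sos, seg.right_force, zi=zi * seg.right_force[0])
    note = f"butterworth(order={spec.order}, cutoff={spec.cutoff}Hz, mode={spec.mode})"
    return seg.with_forces(np.asarray(left), np.asarray(right), note=note)


def smooth_table(table: SegmentTable, spec: FilterSpec = FilterSpec()) -> SegmentTable:
    return SegmentTable(
        [smooth_segment(s, spec) for s in table],
        provenance=table.provenance + f" | smoothed {spec.mode} fc={spec.cutoff}Hz",
    )


# ---------------------------------------------------------------------------
# Expert thresholds


@dataclass(frozen=True)
class ExpertThresholds:
    """1st/99th percentile bounds of expert segment statistics.

    Statistics are the per-segment maximum force, minimum force (both on the
    analysis channel, Newtons) and completion time (seconds).  Percentiles
    use the linear-interpolation convention.
    """

    max_force_p1: float
    max_force_p99: float
    min_force_p1: float
    min_force_p99: float
    duration_p1: float
    duration_p99: float
    n_expert_segments: int
    channel: str = DEFAULT_ANALYSIS_CHANNEL

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ExpertThresholds":
        return cls(**json.loads(Path(path).read_text()))


def segment_statistics(table: SegmentTable, channel: str = DEFAULT_ANALYSIS_CHANNEL) -> pd.DataFrame:
    """Per-segment (max force, min force, duration) on the analysis channel."""
    rows = []
    for s in table:
        x = s.channel(channel)
        rows.append(
            {
                "segment_id": s.segment_id,
                "experience": s.experience,
                "max_force": float(np.max(x)),
                "min_force": float(np.min(x)),
                "duration": s.duration,
            }
        )
    return pd.DataFrame(rows, columns=["segment_id", "experience", "max_force", "min_force", "duration"])


def fit_expert_thresholds(
    table: SegmentTable, channel: str = DEFAULT_ANALYSIS_CHANNEL
) -> ExpertThresholds:
    """Fit [p1, p99] bounds from the Expert segments of a table."""
    stats = segment_statistics(table, channel)
    expert = stats[stats["experience"] == "Expert"]
    if len(expert) < 2:
        raise FittingError(
            f"need >= 2 Expert segments to fit thresholds, found {len(expert)}"
        )
    p = {
        col: np.percentile(expert[col].to_numpy(), [1, 99], method="linear")
        for col in ("max_force", "min_force", "duration")
    }
    return ExpertThresholds(
        max_force_p1=float(p["max_force"][0]),
        max_force_p99=float(p["max_force"][1]),
        min_force_p1=float(p["min_force"][0]),
        min_force_p99=float(p["min_force"][1]),
        duration_p1=float(p["duration"][0]),
        duration_p99=float(p["duration"][1]),
        n_expert_segments=len(expert),
        channel=channel,
    )


def flag_outliers(table: SegmentTable, thr: ExpertThresholds) -> pd.DataFrame:
    """Flag segments whose statistics leave the expert percentile bands.

    A segment is an outlier iff ANY of its max force, min force or duration
    falls outside the corresponding [p1, p99] interval.  Returns a frame with
    ``segment_id``, ``flagged`` and a ``reasons`` list naming the criteria
    that fired (``max_force_high``, ``duration_low``, ...).
    """
    stats = segment_statistics(table, thr.channel)
    bounds = {
        "max_force": (thr.max_force_p1, thr.max_force_p99),
        "min_force": (thr.min_force_p1, thr.min_force_p99),
        "duration": (thr.duration_p1, thr.duration_p99),
    }
    reasons_col = []
    for _, row in stats.iterrows():
        reasons = []
        for stat, (lo, hi) in bounds.items():
            if row[stat] < lo:
                reasons.append(f"{stat}_low")
            elif row[stat] > hi:
                reasons.append(f"{stat}_high")
        reasons_col.append(reasons)
    out = stats[["segment_id"]].copy()
    out["flagged"] = [bool(r) for r in reasons_col]
    out["reasons"] = reasons_col
    return out


def remove_outliers(table: SegmentTable, thr: ExpertThresholds) -> SegmentTable:
    """Pure filter dropping the segments :func:`flag_outliers` marks."""
    flags = flag_outliers(table, thr)
    flagged = set(flags.loc[flags["flagged"], "segment_id"])
    return SegmentTable(
        [s for s in table if s.segment_id not in flagged],
        provenance=table.provenance + f" | removed {len(flagged)} outliers",
    )
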