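"""Expert-baseline performance gauges.

The dashboard compares a surgeon against the expert surgeon on four
representative segment metrics, all drawn from the feature table:

* ``completion_time``  <- ``duration`` (seconds)
* ``force_range``      <- ``range`` (Newtons)
* ``variability_index``<- ``fluctuation`` (mean-crossing rate, [0, 1])
* ``uncertainty_index``<- ``spectral_entropy`` ([0, 1])

A baseline is the mean and sample SD of each metric over all Expert
segments; a gauge panel aggregates one surgeon's segments over a selected
case range and reports each metric with its z-score against the baseline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FittingError, ValidationError

#: gauge metric -> feature-table column
METRIC_FEATURES: dict[str, str] = {
    "completion_time": "duration",
    "force_range": "range",
    "variability_index": "fluctuation",
    "uncertainty_index": "spectral_entropy",
}


@dataclass
class ExpertBaseline:
    """Per-metric expert mean and sample SD."""

    metrics: dict[str, dict[str, float]]  # metric -> {expert_mean, expert_sd}
    n_expert_segments: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"metrics": self.metrics, "n_expert_segments": self.n_expert_segments}, indent=1)
        )


@dataclass
class GaugePanel:
    """One surgeon's metric values and z-scores against the expert baseline."""

    surgeon_id: str
    case_range: list[str]
    n_segments: int
    metrics: dict[str, dict[str, float]]  # metric -> {surgeon_value, expert_mean, expert_sd, z_score}

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "surgeon_id": self.surgeon_id,
                    "case_range": self.case_range,
                    "n_segments": self.n_segments,
                    "metrics": self.metrics,
                },
                indent=1,
                default=float,
            )
        )


def compute_baseline(features: pd.DataFrame) -> ExpertBaseline:
    """Expert mean/SD of the four gauge metrics from a feature table."""
    expert = features[features["experience"] == "Expert"]
    if expert.empty:
        raise FittingError("no Expert rows in the feature table")
    metrics = {}
    for metric, col in METRIC_FEATURES.items():
        vals = expert[col].dropna().to_numpy(dtype=float)
        if len(vals) == 0:
            raise FittingError(f"no usable Expert values for metric {metric} ({col})")
        sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        metrics[metric] = {"expert_mean": float(np.mean(vals)), "expert_sd": sd}
    return ExpertBaseline(metrics=metrics, n_expert_segments=len(expert))


def gauge_panel(
    features: pd.DataFrame,
    surgeon_id: str,
    case_range: list[str] | None,
    baseline: ExpertBaseline,
) -> GaugePanel:
    """Gauge metrics for one surgeon over a selected set of cases.

    ``case_range`` of None selects all of the surgeon's cases.  The surgeon
    value is the unweighted mean over the selected segments; z-score is
    (value - expert_mean) / expert_sd, not-available when expert_sd is 0.
    """
    sel = features[features["surgeon_id"] == surgeon_id]
    if case_range is not None:
        sel = sel[sel["case_id"].isin(case_range)]
    if sel.empty:
        raise ValidationError(
            f"surgeon {surgeon_id!r} has no segments in case range {case_range!r}"
        )
    cases = sorted(sel["case_id"].unique()) if case_range is None else list(case_range)
    metrics = {}
    for metric, col in METRIC_FEATURES.items():
        base = baseline.metrics[metric]
        vals = sel[col].dropna().to_numpy(dtype=float)
        value = float(np.mean(vals)) if len(vals) else float("nan")
        sd = base["expert_sd"]
        z = (value - base["expert_mean"]) / sd if sd > 0 and np.isfinite(value) else float("nan")
        metrics[metric] = {
            "surgeon_value": value,
            "expert_mean": base["expert_mean"],
            "expert_sd": sd,
            "z_score": z,
        }
    return GaugePanel(
        surgeon_id=surgeon_id, case_range=cases, n_segments=len(sel), metrics=metrics
    )
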