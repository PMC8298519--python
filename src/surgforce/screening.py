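"""Per-feature two-way ANOVA screening (experience x task) and subset selection.

Each of the 37 features is screened with an independent-measures two-way
ANOVA with interaction, experience (Expert/Novice) and task (5 labels) as
grouping factors.  Because real segment layouts are heavily unbalanced,
Type II sums of squares are used; on a balanced design they coincide with
the classical decomposition.  Post-hoc task contrasts use Tukey's HSD.

The modelling subset can be selected either by the fixed rule (drop the 12
features that showed no useful group separation, keeping 25) or by a
p-value threshold on the main effects.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .catalog import FEATURE_CATALOG, FIXED_SUBSET_EXCLUSIONS
from .errors import ConfigurationError, ParameterError

NA = float("nan")


@dataclass
class ScreeningReport:
    """ANOVA rows per feature, post-hoc task contrasts, selected subset."""

    rows: pd.DataFrame
    posthoc: dict[str, pd.DataFrame] = field(default_factory=dict)
    selected: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "rows": self.rows.to_dict(orient="records"),
            "posthoc": {k: v.to_dict(orient="records") for k, v in self.posthoc.items()},
            "selected": self.selected,
        }
        Path(path).write_text(json.dumps(payload, indent=1, default=float))

    def to_csv(self, path: str | Path) -> None:
        self.rows.to_csv(path, index=False)


def _anova_one(df: pd.DataFrame, feature: str) -> dict[str, float]:
    """Type II two-way ANOVA with interaction for one feature column."""
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    sub = df[["experience", "task", feature]].dropna().rename(columns={feature: "value"})
    row = {
        "feature": feature,
        "f_experience": NA,
        "p_experience": NA,
        "f_task": NA,
        "p_task": NA,
        "f_interaction": NA,
        "p_interaction": NA,
        "n_used": len(sub),
    }
    if sub["experience"].nunique() < 2 or sub["task"].nunique() < 2:
        raise ConfigurationError(
            f"feature {feature}: both factors need >= 2 observed levels"
        )
    n_cells = sub.groupby(["experience", "task"], observed=True).ngroups
    if len(sub) <= n_cells:
        return row  # no residual degrees of freedom
    if float(np.var(sub["value"].to_numpy())) == 0.0:
        return row  # zero residual variance: F undefined
    model = smf.ols("value ~ C(experience) * C(task)", data=sub).fit()
    with np.errstate(divide="ignore", invalid="ignore"):
        tab = sm.stats.anova_lm(model, typ=2)
    def pick(key):
        return float(tab.loc[key, "F"]), float(tab.loc[key, "PR(>F)"])
    row["f_experience"], row["p_experience"] = pick("C(experience)")
    row["f_task"], row["p_task"] = pick("C(task)")
    row["f_interaction"], row["p_interaction"] = pick("C(experience):C(task)")
    return row


def anova_screen(
    features: pd.DataFrame,
    feature_names: list[str] | None = None,
    bh_adjust: bool = False,
) -> ScreeningReport:
    """Two-way ANOVA per feature; optionally Benjamini-Hochberg across features.

    ``features`` is a feature table (metadata columns + feature columns).
    Complete cases are used per feature.  Raw per-feature p-values are
    reported by default; ``bh_adjust`` adds ``p_experience_adj``/``p_task_adj``
    columns without altering the raw ones.
    """
    names = feature_names or [c for c in FEATURE_CATALOG if c in features.columns]
    if not names:
        raise ConfigurationError("no feature columns found in the table")
    rows = pd.DataFrame([_anova_one(features, f) for f in names])
    if bh_adjust:
        from statsmodels.stats.multitest import multipletests

        for eff in ("p_experience", "p_task"):
            p = rows[eff].to_numpy()
            ok = np.isfinite(p)
            adj = np.full_like(p, NA)
            if ok.any():
                adj[ok] = multipletests(p[ok], method="fdr_bh")[1]
            rows[f"{eff}_adj"] = adj
    return ScreeningReport(rows=rows)


def posthoc_tasks(features: pd.DataFrame, feature_name: str, alpha: float = 0.05) -> pd.DataFrame:
    """All pairwise task-mean contrasts with Tukey HSD adjusted p-values."""
    from itertools import combinations

    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    sub = features[["task", feature_name]].dropna()
    if sub["task"].nunique() < 2:
        raise ConfigurationError(f"feature {feature_name}: need >= 2 task levels")
    res = pairwise_tukeyhsd(sub[feature_name].to_numpy(), sub["task"].to_numpy(), alpha=alpha)
    pairs = list(combinations(res.groupsunique, 2))
    return pd.DataFrame(
        {
            "task_a": [a for a, _ in pairs],
            "task_b": [b for _, b in pairs],
            "difference": np.asarray(res.meandiffs, dtype=float),
            "p_adjusted": np.asarray(res.pvalues, dtype=float),
        }
    )


def select_model_subset(
    report: ScreeningReport | None,
    mode: str = "fixed",
    alpha: float = 0.05,
    catalogue: tuple[str, ...] = FEATURE_CATALOG,
) -> list[str]:
    """Choose the modelling feature subset.

    ``fixed`` drops the 12 fixed exclusions from the catalogue,
    returning the remaining 25 in catalogue order (idempotent; needs no
    report).  ``threshold`` keeps features whose ANOVA shows any main-effect
    p-value below ``alpha``.
    """
    if mode == "fixed":
        return [f for f in catalogue if f not in FIXED_SUBSET_EXCLUSIONS]
    if mode == "threshold":
        if report is None:
            raise ParameterError("threshold mode requires a ScreeningReport")
        keep = []
        for _, row in report.rows.iterrows():
            ps = [row["p_experience"], row["p_task"]]
            if any(np.isfinite(p) and p < alpha for p in ps):
                keep.append(row["feature"])
        return keep
    raise ParameterError(f"unknown selection mode {mode!r}; use fixed or threshold")
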