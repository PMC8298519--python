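"""Expert-vs-Novice skill classifier.

Pipeline: median imputation -> standardization -> PCA -> RBF-kernel SVM, with
cost/gamma chosen by cross-validated grid search on the training split only.
The train/test split is stratified and seeded; every preprocessing step is
fitted inside the pipeline so nothing leaks from the test split.

Reported metrics: AUC from decision scores on the test split, train/test
accuracy, sensitivity (recall of Expert) and specificity (recall of Novice).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.impute import SimpleImputer
from sklearn.metrics import accuracy_score, roc_auc_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .catalog import FEATURE_CATALOG, FIXED_SUBSET_EXCLUSIONS
from .errors import ConfigurationError, ParameterError, SchemaError

#: the grid value the dashboard's tuned RBF model settled on (0.1 * 10^0.1)
TUNED_COST_GAMMA = 0.1 * 10 ** 0.1

DEFAULT_SUBSET = tuple(f for f in FEATURE_CATALOG if f not in FIXED_SUBSET_EXCLUSIONS)


@dataclass(frozen=True)
class SkillModelConfig:
    feature_subset: tuple[str, ...] = DEFAULT_SUBSET
    pca_variance_retained: float = 0.95
    cost_grid: tuple[float, ...] = (0.01, 0.1, TUNED_COST_GAMMA, 1.0, 10.0)
    gamma_grid: tuple[float, ...] = (0.01, 0.1, TUNED_COST_GAMMA, 1.0)
    test_fraction: float = 0.30
    cv_folds: int = 5
    class_weight: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.cost_grid or not self.gamma_grid:
            raise ParameterError("cost/gamma grids must be non-empty")
        if any(c <= 0 for c in self.cost_grid) or any(g <= 0 for g in self.gamma_grid):
            raise ParameterError("grid entries must be positive")
        if not 0 < self.test_fraction < 1:
            raise ParameterError("test_fraction must be in (0, 1)")


@dataclass
class SkillModelResult:
    auc: float
    train_accuracy: float
    test_accuracy: float
    sensitivity: float
    specificity: float
    best_cost: float
    best_gamma: float
    n_components_used: int
    n_train: int
    n_test: int
    seed: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))


@dataclass
class FittedSkillModel:
    pipeline: Pipeline
    feature_names: tuple[str, ...]
    classes: tuple[str, ...]

    def _matrix(self, features: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.feature_names if f not in features.columns]
        if missing:
            raise SchemaError(f"feature table is missing model columns {missing}")
        return features.loc[:, list(self.feature_names)].to_numpy(dtype=float)

    def predict(self, features: pd.DataFrame) -> pd.DataFrame:
        """Per-segment class label and decision score (monotone in P(Expert))."""
        X = self._matrix(features)
        labels = self.pipeline.predict(X)
        scores = self.pipeline.decision_function(X)
        out = pd.DataFrame({"label": labels, "score": scores})
        if "segment_id" in features.columns:
            out.insert(0, "segment_id", features["segment_id"].to_numpy())
        return out


def _check_features(features: pd.DataFrame, subset) -> list[str]:
    missing = [f for f in subset if f not in features.columns]
    if missing:
        raise SchemaError(f"feature table is missing columns {missing}")
    return list(subset)


def train_skill_model(
    features: pd.DataFrame, config: SkillModelConfig = SkillModelConfig()
) -> tuple[SkillModelResult, FittedSkillModel]:
    """Fit the standardize->PCA->RBF-SVM skill classifier.

    ``features`` must carry an ``experience`` column with both classes and
    the configured feature subset.  Fully reproducible given ``config.seed``.
    """
    cols = _check_features(features, config.feature_subset)
    y = features["experience"].to_numpy()
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ConfigurationError("both Expert and Novice segments are required")
    if counts.min() < config.cv_folds:
        raise ConfigurationError(
            f"every class needs >= cv_folds={config.cv_folds} segments; got {dict(zip(classes, counts))}"
        )
    X = features.loc[:, cols].to_numpy(dtype=float)
    X_tr, X_te, y_tr, y_te = train_test_split(
        X,
        y,
        test_size=config.test_fraction,
        stratify=y,
        random_state=config.seed,
    )
    pipe = Pipeline(
        [
            ("impute", SimpleImputer(strategy="median")),
            ("scale", StandardScaler()),
            ("pca", PCA(n_components=config.pca_variance_retained, svd_solver="full")),
            ("svm", SVC(kernel="rbf", class_weight=config.class_weight)),
        ]
    )
    grid = GridSearchCV(
        pipe,
        param_grid={"svm__C": list(config.cost_grid), "svm__gamma": list(config.gamma_grid)},
        scoring="accuracy",
        cv=StratifiedKFold(config.cv_folds, shuffle=True, random_state=config.seed),
        n_jobs=1,
    )
    grid.fit(X_tr, y_tr)
    best: Pipeline = grid.best_estimator_
    # decision_function is monotone in P(second class); orient toward Expert
    expert_sign = 1.0 if best.classes_[1] == "Expert" else -1.0
    scores_te = expert_sign * best.decision_function(X_te)
    pred_tr = best.predict(X_tr)
    pred_te = best.predict(X_te)
    sens = accuracy_score(y_te[y_te == "Expert"], pred_te[y_te == "Expert"])
    spec = accuracy_score(y_te[y_te == "Novice"], pred_te[y_te == "Novice"])
    result = SkillModelResult(
        auc=float(roc_auc_score((y_te == "Expert").astype(int), scores_te)),
        train_accuracy=float(accuracy_score(y_tr, pred_tr)),
        test_accuracy=float(accuracy_score(y_te, pred_te)),
        sensitivity=float(sens),
        specificity=float(spec),
        best_cost=float(grid.best_params_["svm__C"]),
        best_gamma=float(grid.best_params_["svm__gamma"]),
        n_components_used=int(best.named_steps["pca"].n_components_),
        n_train=len(y_tr),
        n_test=len(y_te),
        seed=config.seed,
    )
    fitted = FittedSkillModel(pipeline=best, feature_names=tuple(cols), classes=tuple(best.classes_))
    return result, fitted


def predict_skill(fitted: FittedSkillModel, features: pd.DataFrame) -> pd.DataFrame:
    """Deterministic per-segment predictions from a fitted skill model."""
    return fitted.predict(features)
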