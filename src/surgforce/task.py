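"""5-class surgical task recognizer on resampled force profiles.

Variable-length segments are mapped to a fixed-length input by linear
interpolation onto ``input_length`` equally spaced points spanning the
segment, then standardized per vector (zero mean, unit variance) so the
network sees shape rather than absolute force level.

Architecture: input -> single-layer LSTM (100 units) -> dropout (0.5) ->
dense (100, ReLU) -> softmax over the 5 task classes, trained with Adam on
categorical cross-entropy.  Training is repeated ``n_repeats`` times with
seeds derived from the master seed, and held-out metrics (cross-entropy
loss, accuracy, and the mean squared error between one-hot labels and the
softmax outputs) are reported as mean (SD) over the repeats.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from .catalog import TASKS
from .errors import ConfigurationError, SchemaError, ValidationError
from .nn import LSTMClassifier, cross_entropy, predict_proba, train_classifier
from .segment_io import ForceSegment, SegmentTable


@dataclass(frozen=True)
class TaskModelConfig:
    input_length: int = 100
    lstm_units: int = 100
    dropout_rate: float = 0.5
    dense_units: int = 100
    n_classes: int = 5
    epochs: int = 200  # desk-scale default; the full-scale setting is 1000
    batch_size: int = 20
    n_repeats: int = 4
    learning_rate: float = 1e-3
    test_fraction: float = 0.30
    channel: str = "right"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.input_length < 8:
            raise ValidationError("input_length must be >= 8")
        if not 0 <= self.dropout_rate < 1:
            raise ValidationError("dropout_rate must be in [0, 1)")
        if self.n_classes != len(TASKS):
            raise ValidationError(f"n_classes is fixed at {len(TASKS)}")


@dataclass
class TaskModelResult:
    per_repeat: list[dict]
    mean_loss: float
    sd_loss: float
    mean_accuracy: float
    sd_accuracy: float
    mean_mse: float
    sd_mse: float
    seed: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))


def resample_segment(seg: ForceSegment, input_length: int = 100, channel: str = "right") -> np.ndarray:
    """Fixed-length, per-vector standardized representation of one segment.

    Linear interpolation onto ``input_length`` equally spaced points spanning
    the segment (endpoints preserved), then zero mean / unit variance; a
    zero-variance segment maps to the zero vector.
    """
    x = seg.channel(channel)
    if len(x) < 2:
        raise ValidationError(f"segment {seg.segment_id} has < 2 samples")
    src = np.linspace(0.0, 1.0, num=len(x))
    dst = np.linspace(0.0, 1.0, num=input_length)
    v = np.interp(dst, src, x)
    sd = v.std()
    # relative guard: an (effectively) constant segment maps to the zero
    # vector rather than amplified float jitter
    if sd <= 1e-12 * max(1.0, float(np.max(np.abs(v)))):
        return np.zeros(input_length)
    return (v - v.mean()) / sd


def _design(table: SegmentTable, config: TaskModelConfig) -> tuple[np.ndarray, np.ndarray]:
    X = np.stack([resample_segment(s, config.input_length, config.channel) for s in table])
    y = np.array([TASKS.index(s.task) for s in table])
    return X[..., None], y  # (n, T, 1)


@dataclass
class FittedTaskModel:
    model: LSTMClassifier
    params: dict
    config: TaskModelConfig

    def predict(self, segments: SegmentTable | list[ForceSegment]) -> pd.DataFrame:
        segs = list(segments)
        X = np.stack(
            [resample_segment(s, self.config.input_length, self.config.channel) for s in segs]
        )[..., None]
        return self.predict_matrix(X, [s.segment_id for s in segs])

    def predict_matrix(self, X: np.ndarray, segment_ids=None) -> pd.DataFrame:
        if X.ndim != 3 or X.shape[1] != self.config.input_length or X.shape[2] != 1:
            raise SchemaError(
                f"expected input of shape (n, {self.config.input_length}, 1), got {X.shape}"
            )
        probs = predict_proba(self.model, self.params, X)
        out = pd.DataFrame(probs, columns=[f"p_{t}" for t in TASKS])
        out.insert(0, "label", [TASKS[i] for i in probs.argmax(axis=1)])
        if segment_ids is not None:
            out.insert(0, "segment_id", segment_ids)
        return out

    def save(self, path: str | Path) -> None:
        np.savez(path, **self.params, __config__=json.dumps(asdict(self.config)))

    @classmethod
    def load(cls, path: str | Path) -> "FittedTaskModel":
        data = np.load(path, allow_pickle=False)
        config = TaskModelConfig(**json.loads(str(data["__config__"])))
        params = {k: data[k] for k in data.files if k != "__config__"}
        model = LSTMClassifier(
            n_features=1,
            lstm_units=config.lstm_units,
            dense_units=config.dense_units,
            n_classes=config.n_classes,
            dropout_rate=config.dropout_rate,
        )
        return cls(model=model, params=params, config=config)


def train_task_model(
    table: SegmentTable, config: TaskModelConfig = TaskModelConfig()
) -> tuple[TaskModelResult, FittedTaskModel]:
    """Train the task recognizer with repeats; report held-out mean (SD) metrics.

    The split is stratified 70/30 (seeded) and shared across repeats; each
    repeat re-initializes and re-trains with a seed derived from the master
    seed.  The returned fitted model is the last repeat's.
    """
    labels = {s.task for s in table}
    missing = set(TASKS) - labels
    if missing:
        raise ConfigurationError(f"all 5 task labels required; missing {sorted(missing)}")
    counts = pd.Series([s.task for s in table]).value_counts()
    if counts.min() < 2:
        raise ConfigurationError("every task class needs >= 2 segments")
    X, y = _design(table, config)
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=config.test_fraction, stratify=y, random_state=config.seed
    )
    model = LSTMClassifier(
        n_features=1,
        lstm_units=config.lstm_units,
        dense_units=config.dense_units,
        n_classes=config.n_classes,
        dropout_rate=config.dropout_rate,
    )
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_repeats)
    per_repeat = []
    params = None
    eye = np.eye(config.n_classes)
    for ss in seeds:
        rng = np.random.Generator(np.random.PCG64(ss))
        params = train_classifier(
            model, X_tr, y_tr, config.epochs, config.batch_size, rng, lr=config.learning_rate
        )
        probs = predict_proba(model, params, X_te)
        onehot = eye[y_te]
        per_repeat.append(
            {
                "loss": cross_entropy(probs, onehot),
                "accuracy": float(np.mean(probs.argmax(axis=1) == y_te)),
                "mse": float(np.mean((onehot - probs) ** 2)),
            }
        )
    def agg(key):
        vals = np.array([r[key] for r in per_repeat])
        sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        return float(np.mean(vals)), sd
    mean_loss, sd_loss = agg("loss")
    mean_acc, sd_acc = agg("accuracy")
    mean_mse, sd_mse = agg("mse")
    result = TaskModelResult(
        per_repeat=per_repeat,
        mean_loss=mean_loss,
        sd_loss=sd_loss,
        mean_accuracy=mean_acc,
        sd_accuracy=sd_acc,
        mean_mse=mean_mse,
        sd_mse=sd_mse,
        seed=config.seed,
    )
    return result, FittedTaskModel(model=model, params=params, config=config)


def predict_task(fitted: FittedTaskModel, segments) -> pd.DataFrame:
    """Per-segment predicted task label and class probabilities."""
    return fitted.predict(segments)
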