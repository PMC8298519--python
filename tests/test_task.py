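"""Task recognizer: resampling contract, LSTM gradients, training behaviour."""

import numpy as np
import pytest

import surgforce.nn as nn
from surgforce.catalog import TASKS
from surgforce.errors import ConfigurationError, SchemaError
from surgforce.nn import LSTMClassifier, cross_entropy
from surgforce.segment_io import SegmentTable
from surgforce.synthetic import default_study_spec, generate, with_counts
from surgforce.task import (
    FittedTaskModel,
    TaskModelConfig,
    predict_task,
    resample_segment,
    train_task_model,
)

from conftest import make_segment

QUICK = TaskModelConfig(epochs=15, n_repeats=1, seed=0)


def small_dataset(n_per_cell=10, seed=0):
    return generate(with_counts(default_study_spec(), n_per_cell), seed=seed).table


class TestResample:
    def test_constant_segment_maps_to_zero_vector(self):
        seg = make_segment(np.full(80, 0.7))
        v = resample_segment(seg, 100)
        assert v.shape == (100,)
        assert np.all(v == 0.0)

    def test_matching_length_ramp_is_standardized_identity(self):
        x = np.linspace(0.0, 1.0, 100)
        v = resample_segment(make_segment(x), 100)
        expected = (x - x.mean()) / x.std()
        assert np.allclose(v, expected)

    def test_57_sample_ramp_interpolates_linearly(self):
        x = np.linspace(2.0, 5.0, 57)
        v = resample_segment(make_segment(x), 100)
        # a linear ramp stays linear under interpolation, so after
        # standardization it equals the standardized target grid
        grid = np.linspace(0.0, 1.0, 100)
        assert np.allclose(v, (grid - grid.mean()) / grid.std())
        raw = np.interp(np.linspace(0, 1, 100), np.linspace(0, 1, 57), x)
        assert raw[0] == pytest.approx(2.0) and raw[-1] == pytest.approx(5.0)


class TestGradients:
    def test_bptt_matches_numerical_gradient(self, monkeypatch):
        monkeypatch.setattr(nn, "DTYPE", np.float64)
        rng = np.random.default_rng(0)
        model = LSTMClassifier(n_features=1, lstm_units=4, dense_units=5, n_classes=3, dropout_rate=0.0)
        params = model.init_params(rng)
        X = rng.normal(size=(3, 7, 1))
        y = np.eye(3)[np.array([0, 2, 1])]

        def loss(p):
            probs, _ = model.forward(p, X, train=False)
            return cross_entropy(probs, y)

        probs, cache = model.forward(params, X, train=False)
        grads = model.backward(params, probs, y, cache)
        for key in params:
            flat = params[key].reshape(-1)
            gflat = grads[key].reshape(-1)
            idx = rng.choice(len(flat), size=min(5, len(flat)), replace=False)
            for i in idx:
                h = 1e-6
                orig = flat[i]
                flat[i] = orig + h
                up = loss(params)
                flat[i] = orig - h
                down = loss(params)
                flat[i] = orig
                numeric = (up - down) / (2 * h)
                assert gflat[i] == pytest.approx(numeric, rel=1e-4, abs=1e-7), key


class TestTraining:
    def test_untrained_network_is_at_chance(self):
        # averaged over 4 random initializations on a balanced 5-class set
        table = small_dataset(30)
        cfg = TaskModelConfig(epochs=0, n_repeats=4, seed=1)
        result, _ = train_task_model(table, cfg)
        assert 0.1 <= result.mean_accuracy <= 0.35

    def test_quick_training_learns_motifs(self):
        table = small_dataset(20, seed=2)
        result, _ = train_task_model(table, QUICK)
        assert result.mean_accuracy >= 0.6

    def test_repeats_reported_with_sd(self):
        table = small_dataset(6, seed=3)
        cfg = TaskModelConfig(epochs=2, n_repeats=4, seed=4)
        result, _ = train_task_model(table, cfg)
        assert len(result.per_repeat) == 4
        accs = [r["accuracy"] for r in result.per_repeat]
        assert result.sd_accuracy == pytest.approx(np.std(accs, ddof=1))

    def test_same_seed_same_metrics(self):
        table = small_dataset(6, seed=5)
        cfg = TaskModelConfig(epochs=3, n_repeats=2, seed=6)
        r1, _ = train_task_model(table, cfg)
        r2, _ = train_task_model(table, cfg)
        assert r1.per_repeat == r2.per_repeat

    def test_missing_class_rejected(self):
        table = small_dataset(6, seed=7)
        partial = SegmentTable([s for s in table if s.task != "Pulling"])
        with pytest.raises(ConfigurationError):
            train_task_model(partial, QUICK)

    def test_label_shuffled_training_does_not_memorize_heldout(self):
        import dataclasses

        table = small_dataset(20, seed=8)
        rng = np.random.default_rng(8)
        tasks = [s.task for s in table]
        shuffled = SegmentTable(
            [dataclasses.replace(s, task=t) for s, t in zip(table, rng.permutation(tasks))]
        )
        result, _ = train_task_model(shuffled, TaskModelConfig(epochs=15, n_repeats=1, seed=9))
        assert 0.1 <= result.mean_accuracy <= 0.35


class TestPrediction:
    @pytest.fixture(scope="class")
    def fitted(self):
        table = small_dataset(20, seed=10)
        _, fitted = train_task_model(table, TaskModelConfig(epochs=25, n_repeats=1, seed=11))
        return table, fitted

    def test_probabilities_sum_to_one(self, fitted):
        table, model = fitted
        pred = predict_task(model, table.segments[:10])
        probs = pred[[f"p_{t}" for t in TASKS]].to_numpy()
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_duplicated_segment_identical_prediction(self, fitted):
        table, model = fitted
        seg = table[0]
        pred = predict_task(model, [seg, seg])
        assert np.array_equal(pred.iloc[0, 2:].to_numpy(float), pred.iloc[1, 2:].to_numpy(float))

    def test_confusion_matrix_diagonally_dominant(self, fitted):
        table, model = fitted
        pred = predict_task(model, table)
        truth = np.array([s.task for s in table])
        for task in TASKS:
            mask = truth == task
            hit_rate = float(np.mean(pred.loc[mask, "label"].to_numpy() == task))
            miss_to_any = max(
                float(np.mean(pred.loc[mask, "label"].to_numpy() == other))
                for other in TASKS
                if other != task
            )
            assert hit_rate > miss_to_any

    def test_wrong_input_length_is_schema_error(self, fitted):
        _, model = fitted
        with pytest.raises(SchemaError):
            model.predict_matrix(np.zeros((2, 50, 1)))

    def test_save_load_round_trip(self, fitted, tmp_path):
        table, model = fitted
        path = tmp_path / "weights.npz"
        model.save(path)
        back = FittedTaskModel.load(path)
        p1 = model.predict(table.segments[:5])
        p2 = back.predict(table.segments[:5])
        assert np.allclose(
            p1.iloc[:, 2:].to_numpy(float), p2.iloc[:, 2:].to_numpy(float)
        )
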