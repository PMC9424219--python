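"""Cross-validation protocol: fold construction, accuracy bookkeeping,
grid enumeration/ranking and final retraining, using cheap stub
classifiers where only the protocol is under test."""

import numpy as np
import pytest

from icgperf.classifier import ModelConfig
from icgperf.model_selection import (
    CVResult,
    Grid,
    cross_validate,
    default_grid,
    grid_search,
    kfold_split,
    results_frame,
    select_and_retrain,
)


class ConstantStub:
    """Always predicts one class; accuracy per fold is hand-computable."""

    def __init__(self, value: int = 1):
        self.value = value

    def fit(self, X, y):
        return self

    def predict(self, X):
        return np.full(len(X), self.value, dtype=int)


class OracleStub:
    """Knows the generating rule label = first feature mod 2: perfect even
    on held-out folds (the protocol, not the learner, is under test)."""

    def fit(self, X, y):
        return self

    def predict(self, X):
        return (np.asarray(X)[:, 0] % 2).astype(int)


class TestKFold:
    def test_470_into_10_folds_of_47(self):
        folds = kfold_split(470, K=10, seed=0)
        assert len(folds) == 10
        assert all(len(f) == 47 for f in folds)

    def test_singleton_folds(self):
        folds = kfold_split(10, K=10, seed=0)
        assert sorted(len(f) for f in folds) == [1] * 10

    def test_disjoint_cover_sizes_differ_by_at_most_one(self):
        folds = kfold_split(47, K=10, seed=3)
        all_idx = np.concatenate(folds)
        assert sorted(all_idx) == list(range(47))
        sizes = {len(f) for f in folds}
        assert max(sizes) - min(sizes) <= 1

    def test_same_seed_identical(self):
        a = kfold_split(100, K=10, seed=7)
        b = kfold_split(100, K=10, seed=7)
        for fa, fb in zip(a, b):
            assert np.array_equal(fa, fb)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            kfold_split(5, K=10)

    def test_stratified_keeps_class_ratio(self):
        y = np.array([1] * 30 + [0] * 70)
        folds = kfold_split(100, K=10, seed=0, y=y, stratified=True)
        for f in folds:
            assert y[f].sum() == 3


class TestCrossValidate:
    def _dataset(self, n=100, frac_ones=0.6, seed=0):
        rng = np.random.default_rng(seed)
        X = np.arange(n, dtype=float)[:, None] * np.ones((1, 3))
        y = np.zeros(n, dtype=int)
        y[rng.choice(n, int(n * frac_ones), replace=False)] = 1
        return X, y

    def test_constant_predictor_accuracy_equals_fold_label_share(self):
        X, y = self._dataset()
        cfg = ModelConfig()
        res = cross_validate(X, y, cfg, K=10, seed=0, model_factory=lambda c: ConstantStub(1))
        folds = kfold_split(len(X), K=10, seed=0)
        expected = [100.0 * y[f].mean() for f in folds]
        assert list(res.fold_accuracies) == pytest.approx(expected)

    def test_perfect_oracle_scores_100_sigma_0(self):
        X = np.arange(100, dtype=float)[:, None] * np.ones((1, 3))
        y = (np.arange(100) % 2).astype(int)
        res = cross_validate(X, y, ModelConfig(), K=10, seed=0,
                             model_factory=lambda c: OracleStub())
        assert res.mean_accuracy == 100.0 and res.sigma == 0.0

    def test_mean_and_sigma_recomputable_from_folds(self):
        X, y = self._dataset(seed=2)
        res = cross_validate(X, y, ModelConfig(), K=10, seed=1,
                             model_factory=lambda c: ConstantStub(0))
        accs = np.array(res.fold_accuracies)
        assert res.mean_accuracy == pytest.approx(accs.mean(), abs=1e-12)
        assert res.sigma == pytest.approx(accs.std(ddof=1), abs=1e-12)

    def test_real_model_on_well_separated_dataset(self, dataset470):
        X, y = dataset470
        cfg = ModelConfig(family="FFNN_1L", neurons_l1=20, activation="relu",
                          epochs=30, seed=0)
        res = cross_validate(X, y, cfg, K=10, seed=0)
        assert res.mean_accuracy >= 95.0

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            cross_validate(np.empty((0, 20)), np.empty(0), ModelConfig())


class TestGrid:
    def test_default_grid_size_and_order(self):
        cfgs = default_grid().configs()
        assert len(cfgs) == 2 + 30 + 81
        assert [c.family for c in cfgs[:2]] == ["SVM", "SVM"]
        assert {c.svm_kernel for c in cfgs[:2]} == {"linear", "gaussian"}
        one_layer = [c for c in cfgs if c.family == "FFNN_1L"]
        assert len(one_layer) == 30
        assert {c.activation for c in one_layer} == {"tanh", "sigmoid", "relu"}
        assert sorted({c.neurons_l1 for c in one_layer}) == list(range(10, 101, 10))
        two_layer = [c for c in cfgs if c.family == "FFNN_2L"]
        assert len(two_layer) == 81
        assert {(c.neurons_l1, c.neurons_l2) for c in two_layer} == set(
            (a, b) for a in (50, 70, 90) for b in (50, 70, 90)
        )

    def test_enumeration_is_deterministic(self):
        assert default_grid().configs(seed=4) == default_grid().configs(seed=4)

    def test_singleton_grid_equals_cross_validate(self):
        rng = np.random.default_rng(0)
        X = np.arange(40, dtype=float)[:, None] * np.ones((1, 2))
        y = (rng.random(40) < 0.5).astype(int)
        grid = Grid(svm_kernels=(), ffnn1_activations=("relu",),
                    ffnn1_neurons=(10,), ffnn2_activations=(), ffnn2_neurons=())
        res = grid_search(X, y, grid, K=5, seed=1, model_factory=lambda c: OracleStub())
        ref = cross_validate(X, y, grid.configs(seed=1)[0], K=5, seed=1,
                             model_factory=lambda c: OracleStub())
        assert len(res) == 1 and res[0] == ref

    def test_ranking_prefers_higher_accuracy(self):
        X = np.arange(40, dtype=float)[:, None] * np.ones((1, 2))
        y = np.array([0, 1] * 20)
        grid = Grid(svm_kernels=("linear", "gaussian"), ffnn1_activations=(),
                    ffnn1_neurons=(), ffnn2_activations=(), ffnn2_neurons=())

        def factory(cfg):
            return OracleStub() if cfg.svm_kernel == "gaussian" else ConstantStub(1)

        res = grid_search(X, y, grid, K=5, seed=0, model_factory=factory)
        assert res[0].config.svm_kernel == "gaussian"
        assert res[0].mean_accuracy == 100.0

    def test_report_frame_columns(self):
        res = [CVResult.from_folds(ModelConfig(), [90.0, 100.0])]
        df = results_frame(res)
        for col in ("family", "kernel", "neurons_l1", "neurons_l2",
                    "activation", "accuracy_mean_pct", "accuracy_sigma_pct"):
            assert col in df.columns


class TestSelectAndRetrain:
    def test_best_config_is_argmax_and_retrained_on_all_data(self):
        X = np.arange(30, dtype=float)[:, None] * np.ones((1, 2))
        y = np.array([0, 1] * 15)
        good = CVResult.from_folds(
            ModelConfig(family="FFNN_1L", neurons_l1=10, activation="relu"),
            [100.0] * 5,
        )
        bad = CVResult.from_folds(
            ModelConfig(family="FFNN_1L", neurons_l1=90, activation="tanh"),
            [60.0] * 5,
        )
        model = select_and_retrain(X, y, [bad, good], model_factory=lambda c: OracleStub())
        assert model.cv_result_.config == good.config
        assert (model.predict(X) == y).all()

    def test_retrained_training_accuracy_at_least_cv_mean(self, extreme_separable_Xy):
        X, y = extreme_separable_Xy
        cfg = ModelConfig(family="FFNN_1L", neurons_l1=10, activation="relu",
                          epochs=40, seed=0)
        res = cross_validate(X, y, cfg, K=5, seed=0)
        model = select_and_retrain(X, y, [res])
        train_acc = 100.0 * (model.predict(X) == y).mean()
        assert train_acc >= res.mean_accuracy

    def test_empty_results_rejected(self):
        with pytest.raises(ValueError):
            select_and_retrain(np.ones((2, 2)), np.array([0, 1]), [])
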