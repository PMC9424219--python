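"""Network architecture arithmetic, training determinism, decision rule,
a numerical gradient check, and the SVM baselines."""

import numpy as np
import pytest

from icgperf.classifier import (
    FeedForwardNetClassifier,
    ModelConfig,
    SVMPerfusionBaseline,
    build_model,
    predict,
    train,
    train_svm_baseline,
)


class TestConfig:
    def test_parameter_count_one_layer_20_relu(self):
        cfg = ModelConfig(family="FFNN_1L", neurons_l1=20, activation="relu")
        # 20*20+20 hidden + 20+1 head
        assert cfg.n_parameters() == 441

    def test_two_layer_architecture(self):
        cfg = ModelConfig(
            family="FFNN_2L", neurons_l1=90, neurons_l2=90, activation=("relu", "relu")
        )
        model = build_model(cfg)
        assert model.hidden_layer_sizes == (90, 90)
        X = np.abs(np.random.default_rng(0).normal(50, 10, size=(12, 20)))
        y = np.array([0, 1] * 6)
        model.set_params(epochs=2).fit(X, y)
        assert model.coefs_[-1].shape == (90, 2)  # softmax head
        assert model._n_out == 2

    def test_unknown_activation_rejected(self):
        with pytest.raises(ValueError, match="activation"):
            build_model(ModelConfig(family="FFNN_1L", neurons_l1=10, activation="gelu"))

    def test_l2_neurons_on_one_layer_family_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(family="FFNN_1L", neurons_l1=10, neurons_l2=10).validate()

    def test_unknown_kernel_rejected(self):
        with pytest.raises(ValueError, match="kernel"):
            ModelConfig(
                family="SVM", neurons_l1=None, activation=None, svm_kernel="poly"
            ).validate()


class TestDecisionRule:
    def test_zero_weights_sigmoid_head_ties_to_inadequate(self):
        m = FeedForwardNetClassifier((4,), "relu", epochs=1, random_state=0)
        m.fit(np.ones((4, 3)), np.array([0, 1, 0, 1]))
        m.coefs_ = [np.zeros_like(w) for w in m.coefs_]
        m.intercepts_ = [np.zeros_like(b) for b in m.intercepts_]
        score, label = predict(m, np.ones(3))
        assert score == 0.5 and label == 0

    def test_zero_weights_softmax_head_ties_to_inadequate(self):
        m = FeedForwardNetClassifier((4, 4), "relu", epochs=1, random_state=0)
        m.fit(np.ones((4, 3)), np.array([0, 1, 0, 1]))
        m.coefs_ = [np.zeros_like(w) for w in m.coefs_]
        m.intercepts_ = [np.zeros_like(b) for b in m.intercepts_]
        score, label = predict(m, np.ones(3))
        assert score == 0.5 and label == 0

    def test_scores_bounded(self, extreme_separable_Xy):
        X, y = extreme_separable_Xy
        m = FeedForwardNetClassifier((8,), "tanh", epochs=5, random_state=1).fit(X, y)
        p = m.decision_scores(X)
        assert np.all((p >= 0) & (p <= 1))
        assert set(m.predict(X)) <= {0, 1}


class TestTraining:
    def test_extreme_separation_reaches_perfect_training_accuracy(
        self, extreme_separable_Xy
    ):
        X, y = extreme_separable_Xy
        m = FeedForwardNetClassifier((20,), "relu", epochs=100, random_state=0)
        m.fit(X, y)
        assert (m.predict(X) == y).mean() == 1.0
        assert len(m.loss_curve_) == 100
        # held-out same-distribution samples classify correctly too
        assert (m.predict(X[::3]) == y[::3]).all()

    def test_single_class_degenerate_fit(self):
        X = np.abs(np.random.default_rng(0).normal(100, 5, size=(10, 20)))
        y = np.ones(10, dtype=int)
        m = FeedForwardNetClassifier((5,), "sigmoid", epochs=30, random_state=0).fit(X, y)
        assert (m.predict(X) == 1).all()

    def test_seeded_determinism_end_to_end(self, extreme_separable_Xy):
        X, y = extreme_separable_Xy
        a = FeedForwardNetClassifier((10,), "relu", epochs=10, random_state=5).fit(X, y)
        b = FeedForwardNetClassifier((10,), "relu", epochs=10, random_state=5).fit(X, y)
        assert np.array_equal(a.decision_scores(X), b.decision_scores(X))
        for wa, wb in zip(a.coefs_, b.coefs_):
            assert np.array_equal(wa, wb)

    def test_nan_and_negative_features_rejected(self):
        m = FeedForwardNetClassifier()
        with pytest.raises(ValueError, match="NaN"):
            m.fit(np.array([[np.nan] * 20]), np.array([1]))
        with pytest.raises(ValueError, match="non-negative"):
            m.fit(np.array([[-1.0] * 20]), np.array([1]))

    def test_wrong_feature_length_rejected(self, trained_small_model):
        with pytest.raises(ValueError, match="features"):
            trained_small_model.predict(np.ones((1, 7)))

    def test_backprop_matches_numerical_gradient(self):
        # one Adam step's raw gradient vs central finite differences
        rng = np.random.default_rng(0)
        X = np.abs(rng.normal(1.0, 0.3, size=(6, 5)))
        y = np.array([0, 1, 1, 0, 1, 0])

        def loss_at(model, W, b):
            a = X
            for li in range(len(model_hidden)):
                z = a @ W[li] + b[li]
                a = np.tanh(z)
            zo = (a @ W[-1] + b[-1])[:, 0]
            p = 1.0 / (1.0 + np.exp(-zo))
            return -np.mean(y * np.log(p) + (1 - y) * np.log(1 - p))

        model_hidden = (4,)
        m = FeedForwardNetClassifier(model_hidden, "tanh", epochs=1, batch_size=6,
                                     learning_rate=0.0, random_state=3)
        # lr=0 keeps weights at init so we can probe the gradient there
        m.fit(X, y)
        W = [w.copy() for w in m.coefs_]
        b = [x.copy() for x in m.intercepts_]

        # analytic gradient (recompute exactly as fit does, full batch)
        z1 = X @ W[0] + b[0]
        a1 = np.tanh(z1)
        zo = (a1 @ W[1] + b[1])[:, 0]
        p = 1.0 / (1.0 + np.exp(-zo))
        dz = ((p - y) / len(y))[:, None]
        gW1 = a1.T @ dz
        d1 = (dz @ W[1].T) * (1 - a1**2)
        gW0 = X.T @ d1

        eps = 1e-6
        for (li, grad) in ((0, gW0), (1, gW1)):
            for idx in [(0, 0), (1, 0), (W[li].shape[0] - 1, W[li].shape[1] - 1)]:
                Wp = [w.copy() for w in W]
                Wm = [w.copy() for w in W]
                Wp[li][idx] += eps
                Wm[li][idx] -= eps
                num = (loss_at(m, Wp, b) - loss_at(m, Wm, b)) / (2 * eps)
                assert num == pytest.approx(grad[idx], rel=1e-4, abs=1e-8)


class TestSVM:
    def test_two_points_one_per_class(self):
        X = np.array([[0.0] * 20, [100.0] * 20])
        y = np.array([0, 1])
        m = train_svm_baseline(X, y, kernel="linear")
        assert np.array_equal(m.predict(X), y)

    @pytest.mark.parametrize("kernel", ["linear", "gaussian"])
    def test_separable_set_trains_perfectly(self, kernel, extreme_separable_Xy):
        X, y = extreme_separable_Xy
        m = train_svm_baseline(X, y, kernel=kernel)
        assert (m.predict(X) == y).mean() == 1.0
        p = m.decision_scores(X)
        assert np.all((p >= 0) & (p <= 1))

    def test_unknown_kernel_rejected(self):
        with pytest.raises(ValueError, match="kernel"):
            train_svm_baseline(np.ones((4, 2)), np.array([0, 1, 0, 1]), kernel="poly")

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="class"):
            SVMPerfusionBaseline().fit(np.ones((3, 2)), np.array([1, 1, 1]))


def test_train_predict_wrappers(extreme_separable_Xy):
    X, y = extreme_separable_Xy
    cfg = ModelConfig(family="FFNN_1L", neurons_l1=10, activation="relu", epochs=20)
    model = train(build_model(cfg), X, y)
    score, label = predict(model, X[0])
    assert 0.0 <= score <= 1.0 and label == int(y[0])
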