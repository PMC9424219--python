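"""Perfusion classifiers: feed-forward networks and SVM baselines.

The model zoo mirrors the clinical evaluation protocol of the method:

* one-hidden-layer feed-forward networks whose output head is a single
  sigmoid unit;
* two-hidden-layer networks with a 2-unit softmax head (per-layer
  activation choices);
* linear- and Gaussian-kernel SVMs as baselines.

Networks train with binary cross-entropy and the Adam optimizer
(mini-batches of 5, 100 epochs by default).  Everything is seeded:
weight initialisation and epoch shuffling draw from one generator, so
the full train-to-predict path is reproducible.  The decision rule is
``label = 1 (adequate) iff score > 0.5``; a tied score of exactly 0.5
is classified inadequate, deliberately flagging uncertain perfusion for
surgeon review.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple, Union

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "ModelConfig",
    "FeedForwardNetClassifier",
    "SVMPerfusionBaseline",
    "build_model",
    "train",
    "predict",
    "train_svm_baseline",
]

N_FEATURES = 20
ACTIVATIONS = ("relu", "tanh", "sigmoid")


def _act(name: str):
    if name == "relu":
        return lambda z: np.maximum(z, 0.0), lambda z, a: (z > 0).astype(float)
    if name == "tanh":
        return np.tanh, lambda z, a: 1.0 - a**2
    if name == "sigmoid":
        sig = lambda z: 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))
        return sig, lambda z, a: a * (1.0 - a)
    raise ValueError(f"unknown activation {name!r}; expected one of {ACTIVATIONS}")


class FeedForwardNetClassifier(BaseEstimator, ClassifierMixin):
    """Small fully connected binary classifier on histogram-area features.

    Parameters
    ----------
    hidden_layer_sizes : tuple of int
        One or two hidden layers.  With one hidden layer the output head
        is a single sigmoid unit; with two it is a 2-unit softmax.
    activation : str or tuple of str
        ``"relu"``, ``"tanh"`` or ``"sigmoid"``; a tuple gives one
        activation per hidden layer.
    epochs, batch_size : int
        Training protocol (defaults 100 and 5).
    learning_rate, beta1, beta2 : float
        Adam hyperparameters at canonical defaults.
    random_state : int
        Seeds weight initialisation and mini-batch shuffling.

    Attributes
    ----------
    coefs_, intercepts_ : lists of ndarray
        Learned weights and biases, input to output.
    loss_curve_ : ndarray, shape (epochs,)
        Mean mini-batch binary cross-entropy per epoch.
    n_parameters_ : int
        Total number of trainable scalars.
    """

    def __init__(
        self,
        hidden_layer_sizes: Tuple[int, ...] = (20,),
        activation: Union[str, Tuple[str, ...]] = "relu",
        epochs: int = 100,
        batch_size: int = 5,
        learning_rate: float = 0.001,
        beta1: float = 0.9,
        beta2: float = 0.999,
        random_state: int = 0,
    ):
        self.hidden_layer_sizes = hidden_layer_sizes
        self.activation = activation
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.beta1 = beta1
        self.beta2 = beta2
        self.random_state = random_state

    # -- architecture --------------------------------------------------

    def _activations(self):
        hidden = tuple(self.hidden_layer_sizes)
        if len(hidden) not in (1, 2):
            raise ValueError(
                f"one or two hidden layers supported, got {len(hidden)}"
            )
        acts = self.activation
        if isinstance(acts, str):
            acts = (acts,) * len(hidden)
        acts = tuple(acts)
        if len(acts) != len(hidden):
            raise ValueError(
                f"{len(acts)} activations for {len(hidden)} hidden layers"
            )
        for a in acts:
            _act(a)
        return hidden, acts

    def _validate_X(self, X, fitting: bool) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (n_samples, n_features)")
        if np.isnan(X).any():
            raise ValueError("features contain NaN")
        if (X < 0).any():
            raise ValueError("histogram-area features must be non-negative")
        if not fitting and X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}"
            )
        return X

    def fit(self, X, y):
        X = self._validate_X(X, fitting=True)
        y = np.asarray(y).astype(int).ravel()
        if not np.isin(y, (0, 1)).all():
            raise ValueError("labels must be binary 0/1")
        if len(y) != len(X):
            raise ValueError("X and y length mismatch")

        hidden, acts = self._activations()
        self.n_features_in_ = X.shape[1]
        self.classes_ = np.array([0, 1])
        n_out = 1 if len(hidden) == 1 else 2
        sizes = (self.n_features_in_,) + hidden + (n_out,)

        rng = np.random.default_rng(self.random_state)
        # uniform fan-in initialisation
        W = [
            rng.uniform(-1.0, 1.0, size=(sizes[i], sizes[i + 1]))
            / np.sqrt(sizes[i])
            for i in range(len(sizes) - 1)
        ]
        b = [np.zeros(sizes[i + 1]) for i in range(len(sizes) - 1)]

        mW = [np.zeros_like(w) for w in W]
        vW = [np.zeros_like(w) for w in W]
        mb = [np.zeros_like(x) for x in b]
        vb = [np.zeros_like(x) for x in b]
        b1, b2, eps, lr = self.beta1, self.beta2, 1e-8, self.learning_rate

        fwd = [_act(a)[0] for a in acts]
        der = [_act(a)[1] for a in acts]
        onehot = np.eye(2)[y] if n_out == 2 else None

        n = len(X)
        losses = []
        t = 0
        for _ in range(self.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            n_batches = 0
            for s in range(0, n, self.batch_size):
                idx = order[s : s + self.batch_size]
                xb, yb = X[idx], y[idx]
                m = len(idx)

                # forward
                zs, activations_ = [], [xb]
                a = xb
                for li in range(len(hidden)):
                    z = a @ W[li] + b[li]
                    a = fwd[li](z)
                    zs.append(z)
                    activations_.append(a)
                z_out = a @ W[-1] + b[-1]

                if n_out == 1:
                    p = 1.0 / (1.0 + np.exp(-np.clip(z_out[:, 0], -500, 500)))
                    pc = np.clip(p, 1e-12, 1 - 1e-12)
                    loss = -np.mean(yb * np.log(pc) + (1 - yb) * np.log(1 - pc))
                    dz = ((p - yb) / m)[:, None]
                else:
                    z_shift = z_out - z_out.max(axis=1, keepdims=True)
                    ez = np.exp(z_shift)
                    p2 = ez / ez.sum(axis=1, keepdims=True)
                    pc = np.clip(p2[np.arange(m), yb], 1e-12, None)
                    loss = -np.mean(np.log(pc))
                    dz = (p2 - onehot[idx]) / m

                grads_W = [None] * len(W)
                grads_b = [None] * len(b)
                grads_W[-1] = activations_[-1].T @ dz
                grads_b[-1] = dz.sum(axis=0)
                delta = dz
                for li in range(len(hidden) - 1, -1, -1):
                    delta = (delta @ W[li + 1].T) * der[li](zs[li], activations_[li + 1])
                    grads_W[li] = activations_[li].T @ delta
                    grads_b[li] = delta.sum(axis=0)

                t += 1
                corr1 = 1.0 - b1**t
                corr2 = 1.0 - b2**t
                for li in range(len(W)):
                    mW[li] = b1 * mW[li] + (1 - b1) * grads_W[li]
                    vW[li] = b2 * vW[li] + (1 - b2) * grads_W[li] ** 2
                    W[li] -= lr * (mW[li] / corr1) / (np.sqrt(vW[li] / corr2) + eps)
                    mb[li] = b1 * mb[li] + (1 - b1) * grads_b[li]
                    vb[li] = b2 * vb[li] + (1 - b2) * grads_b[li] ** 2
                    b[li] -= lr * (mb[li] / corr1) / (np.sqrt(vb[li] / corr2) + eps)

                epoch_loss += loss
                n_batches += 1
            losses.append(epoch_loss / max(n_batches, 1))

        self.coefs_ = W
        self.intercepts_ = b
        self.loss_curve_ = np.asarray(losses)
        self.n_parameters_ = int(
            sum(w.size for w in W) + sum(x.size for x in b)
        )
        self._n_out = n_out
        return self

    # -- inference -----------------------------------------------------

    def decision_scores(self, X) -> np.ndarray:
        """Probability of adequate perfusion for each row of ``X``."""
        check_is_fitted(self, "coefs_")
        X = self._validate_X(X, fitting=False)
        hidden, acts = self._activations()
        a = X
        for li in range(len(hidden)):
            a = _act(acts[li])[0](a @ self.coefs_[li] + self.intercepts_[li])
        z = a @ self.coefs_[-1] + self.intercepts_[-1]
        if self._n_out == 1:
            return 1.0 / (1.0 + np.exp(-np.clip(z[:, 0], -500, 500)))
        z = z - z.max(axis=1, keepdims=True)
        ez = np.exp(z)
        return (ez / ez.sum(axis=1, keepdims=True))[:, 1]

    def predict_proba(self, X) -> np.ndarray:
        p1 = self.decision_scores(X)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X) -> np.ndarray:
        return (self.decision_scores(X) > 0.5).astype(int)


class SVMPerfusionBaseline(BaseEstimator, ClassifierMixin):
    """Linear- or Gaussian-kernel SVM baseline on the raw count features.

    The Gaussian bandwidth uses the median heuristic: gamma = 1/(2 m^2)
    with m the median Euclidean distance between training points
    (subsampled to 500 points on large sets).  Features are
    used unscaled by default, mirroring the evaluation protocol of the
    networks; ``standardize=True`` enables z-scoring.
    """

    def __init__(self, kernel: str = "linear", standardize: bool = False, random_state: int = 0):
        self.kernel = kernel
        self.standardize = standardize
        self.random_state = random_state

    def fit(self, X, y):
        if self.kernel not in ("linear", "gaussian"):
            raise ValueError(
                f"unknown kernel {self.kernel!r}; expected 'linear' or 'gaussian'"
            )
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(int).ravel()
        if len(np.unique(y)) < 2:
            raise ValueError("SVM training needs at least one sample of each class")
        self.n_features_in_ = X.shape[1]
        self.classes_ = np.array([0, 1])
        self.scaler_ = StandardScaler().fit(X) if self.standardize else None
        Xs = self.scaler_.transform(X) if self.scaler_ is not None else X
        if self.kernel == "gaussian":
            sub = Xs if len(Xs) <= 500 else Xs[
                np.random.default_rng(self.random_state).choice(len(Xs), 500, replace=False)
            ]
            d = np.sqrt(
                np.maximum(
                    ((sub[:, None, :] - sub[None, :, :]) ** 2).sum(-1), 0.0
                )
            )
            med = np.median(d[np.triu_indices_from(d, k=1)])
            gamma = 1.0 / (2.0 * med**2) if med > 0 else "scale"
            self.svc_ = SVC(kernel="rbf", gamma=gamma, random_state=self.random_state)
        else:
            self.svc_ = SVC(kernel="linear", random_state=self.random_state)
        self.svc_.fit(Xs, y)
        return self

    def decision_scores(self, X) -> np.ndarray:
        """Monotone sigmoid link of the decision function, in [0, 1]."""
        check_is_fitted(self, "svc_")
        X = np.asarray(X, dtype=float)
        if self.scaler_ is not None:
            X = self.scaler_.transform(X)
        d = self.svc_.decision_function(X)
        return 1.0 / (1.0 + np.exp(-np.clip(d, -500, 500)))

    def predict_proba(self, X) -> np.ndarray:
        p1 = self.decision_scores(X)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X) -> np.ndarray:
        return (self.decision_scores(X) > 0.5).astype(int)


# -- configuration records and thin functional wrappers ----------------


@dataclass(frozen=True)
class ModelConfig:
    """One entry of the model zoo, buildable into an estimator.

    ``family`` is FFNN_1L (single hidden layer, sigmoid head), FFNN_2L
    (two hidden layers, softmax head) or SVM.  NN fields are ignored for
    SVM and vice versa.
    """

    family: str = "FFNN_1L"
    neurons_l1: Optional[int] = 20
    neurons_l2: Optional[int] = None
    activation: Union[str, Tuple[str, str], None] = "relu"
    svm_kernel: Optional[str] = None
    epochs: int = 100
    batch_size: int = 5
    seed: int = 0

    def validate(self) -> None:
        if self.family not in ("FFNN_1L", "FFNN_2L", "SVM"):
            raise ValueError(f"unknown model family {self.family!r}")
        if self.family == "FFNN_1L":
            if not self.neurons_l1 or self.neurons_l2 is not None:
                raise ValueError("FFNN_1L takes neurons_l1 only")
            if not isinstance(self.activation, str):
                raise ValueError("FFNN_1L takes a single activation")
            _act(self.activation)
        elif self.family == "FFNN_2L":
            if not self.neurons_l1 or not self.neurons_l2:
                raise ValueError("FFNN_2L needs neurons_l1 and neurons_l2")
            acts = (
                (self.activation,) * 2
                if isinstance(self.activation, str)
                else tuple(self.activation)
            )
            if len(acts) != 2:
                raise ValueError("FFNN_2L takes one or two activations")
            for a in acts:
                _act(a)
        else:
            if self.svm_kernel not in ("linear", "gaussian"):
                raise ValueError(
                    f"SVM kernel must be 'linear' or 'gaussian', got {self.svm_kernel!r}"
                )

    def build(self):
        """Instantiate the (unfitted) estimator this config describes."""
        self.validate()
        if self.family == "SVM":
            return SVMPerfusionBaseline(kernel=self.svm_kernel, random_state=self.seed)
        if self.family == "FFNN_1L":
            hidden: Tuple[int, ...] = (self.neurons_l1,)
        else:
            hidden = (self.neurons_l1, self.neurons_l2)
        return FeedForwardNetClassifier(
            hidden_layer_sizes=hidden,
            activation=self.activation,
            epochs=self.epochs,
            batch_size=self.batch_size,
            random_state=self.seed,
        )

    def n_parameters(self, n_features: int = N_FEATURES) -> int:
        """Trainable-parameter count for NN families (0 for SVM)."""
        self.validate()
        if self.family == "SVM":
            return 0
        hidden = (
            (self.neurons_l1,)
            if self.family == "FFNN_1L"
            else (self.neurons_l1, self.neurons_l2)
        )
        sizes = (n_features,) + hidden + (1 if len(hidden) == 1 else 2,)
        return sum(
            sizes[i] * sizes[i + 1] + sizes[i + 1] for i in range(len(sizes) - 1)
        )

    def describe(self) -> dict:
        return {
            "family": self.family,
            "kernel": self.svm_kernel or "",
            "neurons_l1": self.neurons_l1 or "",
            "neurons_l2": self.neurons_l2 or "",
            "activation": (
                self.activation
                if isinstance(self.activation, str)
                else "+".join(self.activation)
            )
            if self.activation
            else "",
        }


def build_model(config: ModelConfig):
    """Unfitted estimator for a :class:`ModelConfig`."""
    return config.build()


def train(model, X, y):
    """Fit an estimator; returns the fitted estimator."""
    return model.fit(np.asarray(X, dtype=float), np.asarray(y))


def predict(model, x) -> Tuple[float, int]:
    """Score and label for a single feature vector.

    Returns ``(score, label)`` with score the probability of adequate
    perfusion and ``label = 1`` iff score strictly exceeds 0.5.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    score = float(model.decision_scores(x)[0])
    return score, int(score > 0.5)


def train_svm_baseline(X, y, kernel: str = "linear", seed: int = 0) -> SVMPerfusionBaseline:
    """Fit an SVM baseline with the given kernel."""
    return SVMPerfusionBaseline(kernel=kernel, random_state=seed).fit(
        np.asarray(X, dtype=float), np.asarray(y)
    )
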