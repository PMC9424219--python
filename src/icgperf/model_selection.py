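"""K-fold cross-validation, hyperparameter grid search and final retraining.

Every candidate configuration is scored by K=10-fold cross-validation:
the data are shuffled into K folds of near-equal size, each fold serves
once as the test set, and the per-fold accuracy (percent correct on the
held-out fold) is summarised as mean +/- 1-sigma repeatability (sample
standard deviation, n-1 denominator).  The grid spans the three network
activation functions by ten hidden-layer widths for one-hidden-layer
networks, activation/width combinations for two-hidden-layer networks,
and linear/Gaussian SVM baselines.  The top configuration (by mean
accuracy; ties broken by smaller sigma, then fewer parameters) is
retrained on the entire dataset for deployment.

Folds are shuffled but not stratified by default; pass
``stratified=True`` when class imbalance makes small folds noisy.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold

from .classifier import ACTIVATIONS, ModelConfig

__all__ = [
    "CVResult",
    "Grid",
    "default_grid",
    "kfold_split",
    "cross_validate",
    "grid_search",
    "select_and_retrain",
    "results_frame",
    "format_report",
]


@dataclass(frozen=True)
class CVResult:
    """Cross-validation outcome for one model configuration."""

    config: ModelConfig
    fold_accuracies: Tuple[float, ...]  # percent correct per held-out fold
    mean_accuracy: float
    sigma: float

    @staticmethod
    def from_folds(config: ModelConfig, accs: Sequence[float]) -> "CVResult":
        accs = tuple(float(a) for a in accs)
        mean = float(np.mean(accs))
        sigma = float(np.std(accs, ddof=1)) if len(accs) > 1 else 0.0
        return CVResult(config, accs, mean, sigma)


@dataclass(frozen=True)
class Grid:
    """Enumerable hyperparameter grid, in documented deterministic order.

    Enumeration order: SVM kernels first, then one-hidden-layer networks
    (activation-major, neurons ascending), then two-hidden-layer
    networks (activation pairs in lexicographic order over
    (relu, sigmoid, tanh), neuron pairs ascending).
    """

    svm_kernels: Tuple[str, ...] = ("linear", "gaussian")
    ffnn1_activations: Tuple[str, ...] = ("tanh", "sigmoid", "relu")
    ffnn1_neurons: Tuple[int, ...] = tuple(range(10, 101, 10))
    ffnn2_activations: Tuple[Tuple[str, str], ...] = tuple(
        itertools.product(ACTIVATIONS, repeat=2)
    )
    ffnn2_neurons: Tuple[Tuple[int, int], ...] = tuple(
        itertools.product((50, 70, 90), repeat=2)
    )
    epochs: int = 100
    batch_size: int = 5

    def configs(self, seed: int = 0) -> List[ModelConfig]:
        out: List[ModelConfig] = []
        common = dict(epochs=self.epochs, batch_size=self.batch_size, seed=seed)
        for kern in self.svm_kernels:
            out.append(
                ModelConfig(
                    family="SVM", neurons_l1=None, neurons_l2=None,
                    activation=None, svm_kernel=kern, **common,
                )
            )
        for act in self.ffnn1_activations:
            for n in self.ffnn1_neurons:
                out.append(
                    ModelConfig(family="FFNN_1L", neurons_l1=n, activation=act, **common)
                )
        for acts in self.ffnn2_activations:
            for n1, n2 in self.ffnn2_neurons:
                out.append(
                    ModelConfig(
                        family="FFNN_2L", neurons_l1=n1, neurons_l2=n2,
                        activation=acts, **common,
                    )
                )
        return out


def default_grid() -> Grid:
    """The full evaluation grid: 2 SVMs + 30 FFNN_1L + 81 FFNN_2L configs."""
    return Grid()


def kfold_split(
    n: int, K: int = 10, seed: int = 0, y: Optional[np.ndarray] = None,
    stratified: bool = False,
) -> List[np.ndarray]:
    """Disjoint shuffled index folds covering 0..n-1, sizes differing by <= 1."""
    if n < K:
        raise ValueError(f"cannot split {n} samples into {K} folds")
    if stratified:
        if y is None:
            raise ValueError("stratified split requires y")
        splitter = StratifiedKFold(n_splits=K, shuffle=True, random_state=seed)
        return [test for _, test in splitter.split(np.zeros(n), y)]
    splitter = KFold(n_splits=K, shuffle=True, random_state=seed)
    return [test for _, test in splitter.split(np.zeros(n))]


def cross_validate(
    X, y, config: ModelConfig, K: int = 10, seed: int = 0,
    stratified: bool = False, model_factory=None,
) -> CVResult:
    """K-fold cross-validation of one configuration.

    Per fold: train on the other K-1 folds, score percent-correct on the
    held-out fold.  ``model_factory`` (config -> estimator) can inject a
    stub classifier for protocol testing; by default ``config.build()``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int).ravel()
    if len(X) == 0:
        raise ValueError("empty dataset")
    folds = kfold_split(len(X), K=K, seed=seed, y=y, stratified=stratified)
    factory = model_factory if model_factory is not None else (lambda c: c.build())
    all_idx = np.arange(len(X))
    accs = []
    for test_idx in folds:
        train_mask = ~np.isin(all_idx, test_idx)
        assert not np.any(train_mask[test_idx]), "fold hygiene violated"
        model = factory(config)
        model.fit(X[train_mask], y[train_mask])
        pred = np.asarray(model.predict(X[test_idx]))
        accs.append(100.0 * np.mean(pred == y[test_idx]))
    return CVResult.from_folds(config, accs)


def _rank_key(r: CVResult):
    return (-r.mean_accuracy, r.sigma, r.config.n_parameters())


def grid_search(
    X, y, grid: Optional[Grid] = None, K: int = 10, seed: int = 0,
    stratified: bool = False, model_factory=None, verbose: bool = False,
) -> List[CVResult]:
    """Cross-validate every grid configuration; return results ranked best-first.

    Ranking: mean accuracy descending, ties broken by smaller sigma,
    then by fewer trainable parameters.
    """
    grid = grid if grid is not None else default_grid()
    configs = grid.configs(seed=seed)
    if not configs:
        raise ValueError("empty grid")
    results = []
    for i, cfg in enumerate(configs):
        res = cross_validate(
            X, y, cfg, K=K, seed=seed, stratified=stratified,
            model_factory=model_factory,
        )
        if verbose:
            d = cfg.describe()
            print(
                f"[{i + 1}/{len(configs)}] {d['family']} {d['kernel']}"
                f" {d['neurons_l1']} {d['neurons_l2']} {d['activation']}"
                f" -> {res.mean_accuracy:.1f} +/- {res.sigma:.1f} %"
            )
        results.append(res)
    return sorted(results, key=_rank_key)


def select_and_retrain(X, y, results: Sequence[CVResult], model_factory=None):
    """Retrain the top-ranked configuration on the full dataset.

    Returns the fitted estimator with its CVResult attached as
    ``cv_result_`` for provenance.
    """
    if not results:
        raise ValueError("no results to select from")
    best = min(results, key=_rank_key)
    factory = model_factory if model_factory is not None else (lambda c: c.build())
    model = factory(best.config)
    model.fit(np.asarray(X, dtype=float), np.asarray(y).astype(int).ravel())
    model.cv_result_ = best
    return model


def results_frame(results: Sequence[CVResult]) -> pd.DataFrame:
    """Report table: one row per configuration, ranked best-first."""
    rows = []
    for r in results:
        row = r.config.describe()
        row["accuracy_mean_pct"] = r.mean_accuracy
        row["accuracy_sigma_pct"] = r.sigma
        row["fold_accuracies"] = ";".join(f"{a:.4f}" for a in r.fold_accuracies)
        rows.append(row)
    return pd.DataFrame(rows)


def format_report(results: Sequence[CVResult]) -> str:
    """Human-readable fixed-width table of the ranked grid results."""
    lines = [
        f"{'family':8s} {'kernel':9s} {'L1':>4s} {'L2':>4s} "
        f"{'activation':14s} {'accuracy (%)':>16s}"
    ]
    for r in results:
        d = r.config.describe()
        lines.append(
            f"{d['family']:8s} {str(d['kernel']):9s} {str(d['neurons_l1']):>4s} "
            f"{str(d['neurons_l2']):>4s} {str(d['activation']):14s} "
            f"{r.mean_accuracy:7.1f} ± {r.sigma:4.1f}"
        )
    return "\n".join(lines)
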