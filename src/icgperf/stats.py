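"""Statistical validation of the activation-function comparison.

The model-selection grid yields, for each activation function, the mean
10-fold CV accuracy at each hidden-layer width.  Whether the activation
choice matters is assessed with a one-way ANOVA (Fisher F test) across
the three groups at significance level alpha = 1%, followed by pairwise
paired t-tests (paired by hidden-layer width) to locate which group
differs.  Tests are two-sided and exact tail probabilities are
computed; decisions are REJECT iff p < alpha.

Degenerate inputs (zero within-group variance, identical paired
differences) raise errors rather than returning sentinel p-values —
a silent p = 0 would fabricate significance.

``load_reference_activation_table`` ships the accuracy grid published
in the clinical evaluation of this method (whose surgical videos are
not publicly available), so the decision logic can be checked against
the published conclusions.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import List, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "StatDecision",
    "one_way_anova",
    "paired_t_test",
    "compare_activation_groups",
    "load_reference_activation_table",
    "decisions_frame",
    "DEFAULT_ALPHA",
]

DEFAULT_ALPHA = 0.01
REJECT = "REJECT"
FAIL_TO_REJECT = "FAIL_TO_REJECT"


@dataclass(frozen=True)
class StatDecision:
    """Outcome of one hypothesis test.

    ``decision`` is REJECT iff ``p_value < alpha``; the null hypothesis
    throughout is that the compared groups come from the same
    population.
    """

    test_name: str
    statistic: float
    p_value: float
    alpha: float
    decision: str

    @staticmethod
    def from_p(test_name: str, statistic: float, p_value: float, alpha: float) -> "StatDecision":
        if not 0.0 <= p_value <= 1.0:
            raise ValueError(f"p-value {p_value} outside [0, 1]")
        return StatDecision(
            test_name=test_name,
            statistic=float(statistic),
            p_value=float(p_value),
            alpha=float(alpha),
            decision=REJECT if p_value < alpha else FAIL_TO_REJECT,
        )


def one_way_anova(groups: Sequence[Sequence[float]], alpha: float = DEFAULT_ALPHA) -> StatDecision:
    """Classical one-way ANOVA (Fisher F test) across >= 2 groups.

    F = between-group mean square / within-group mean square, with
    p from the F(k-1, N-k) upper tail.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2:
        raise ValueError("ANOVA needs at least two groups")
    for g in arrs:
        if len(g) < 2:
            raise ValueError("each group needs at least two values")
    if all(np.ptp(g) == 0 for g in arrs):
        raise ValueError("zero within-group variance in every group: F undefined")
    f, p = sps.f_oneway(*arrs)
    if not np.isfinite(f):
        raise ValueError("degenerate ANOVA input (zero within-group variance)")
    return StatDecision.from_p("one_way_anova", f, p, alpha)


def paired_t_test(a: Sequence[float], b: Sequence[float], alpha: float = DEFAULT_ALPHA) -> StatDecision:
    """Two-sided paired t-test on matched observations.

    t = mean(d) / (sd(d)/sqrt(n)) on the differences d = a - b, with
    the two-sided p from Student's t with n-1 degrees of freedom.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired test needs two equal-length 1-D samples")
    if len(a) < 2:
        raise ValueError("paired test needs at least two pairs")
    d = a - b
    if np.ptp(d) == 0:
        raise ValueError(
            "all paired differences identical (zero variance): t undefined"
        )
    t, p = sps.ttest_rel(a, b)
    return StatDecision.from_p("paired_t_test", t, p, alpha)


def compare_activation_groups(
    table: pd.DataFrame, alpha: float = DEFAULT_ALPHA
) -> List[StatDecision]:
    """The full activation-comparison protocol on a tanh/sigmoid/relu table.

    ``table`` must carry columns ``tanh``, ``sigmoid`` and ``relu`` of
    mean accuracies, one row per hidden-layer width.  Returns, in order:
    the ANOVA across all three groups, then the paired t-tests
    tanh-sigmoid, tanh-relu and relu-sigmoid.
    """
    cols = ("tanh", "sigmoid", "relu")
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"table missing columns {missing}")
    tanh = table["tanh"].to_numpy(float)
    sigm = table["sigmoid"].to_numpy(float)
    relu = table["relu"].to_numpy(float)
    out = [one_way_anova([tanh, sigm, relu], alpha=alpha)]
    for name, (x, z) in {
        "t_tanh_sigmoid": (tanh, sigm),
        "t_tanh_relu": (tanh, relu),
        "t_relu_sigmoid": (relu, sigm),
    }.items():
        d = paired_t_test(x, z, alpha=alpha)
        out.append(StatDecision(name, d.statistic, d.p_value, d.alpha, d.decision))
    return out


def load_reference_activation_table() -> pd.DataFrame:
    """Published per-activation CV accuracy grid (clinical evaluation).

    Columns ``neurons, tanh, sigmoid, relu``: mean 10-fold CV accuracy
    (%) of one-hidden-layer networks at hidden widths 10..100.
    """
    with resources.files("icgperf.data").joinpath(
        "reference_activation_accuracies.csv"
    ).open() as fh:
        return pd.read_csv(fh)


def decisions_frame(decisions: Sequence[StatDecision]) -> pd.DataFrame:
    """Report table mirroring the published statistical summary layout."""
    return pd.DataFrame(
        [
            {
                "test": d.test_name,
                "H0": "same distribution",
                "alpha_pct": 100.0 * d.alpha,
                "p_value_pct": 100.0 * d.p_value,
                "decision": "Reject" if d.decision == REJECT else "Fail to reject",
            }
            for d in decisions
        ]
    )
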