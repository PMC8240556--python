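"""Elementary tests with exact small-sample behavior.

The group comparisons behind the figures: two-sided Mann-Whitney U
(exact enumeration for small tie-free samples, normal approximation with
tie and continuity corrections otherwise), the Wilcoxon signed-rank test as
the paired analogue, Fisher's exact test on 2x2 tables (probability-mass
two-sided rule), and the linear-interpolation percentile used for the
negative-control cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .core import ValidationError

EXACT_MWU_MAX_N = 12
EXACT_SIGNED_RANK_MAX_N = 15


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str  # "exact" | "approximate"
    sidedness: str = "two-sided"

    def __post_init__(self):
        if not (0.0 < self.p_value <= 1.0):
            raise ValidationError(f"p value {self.p_value} outside (0, 1]")


def _has_ties(values) -> bool:
    v = np.asarray(values, dtype=float)
    return len(np.unique(v)) < len(v)


def mann_whitney_u(x, y) -> TestResult:
    """Two-sided Mann-Whitney U (rank-sum) test.

    Exact when n_x + n_y <= 12 and the pooled sample is tie-free; otherwise
    the normal approximation with tie correction and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("mann_whitney_u requires non-empty groups")
    exact = (x.size + y.size) <= EXACT_MWU_MAX_N and not _has_ties(np.concatenate([x, y]))
    res = sps.mannwhitneyu(
        x, y,
        alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        method="exact" if exact else "approximate",
    )


def signed_rank_paired(differences) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped before ranking; exact when the remaining
    n <= 15 with tie-free absolute values.
    """
    d = np.asarray(differences, dtype=float)
    d = d[d != 0]
    if d.size == 0:
        raise ValidationError("all differences are zero")
    exact = d.size <= EXACT_SIGNED_RANK_MAX_N and not _has_ties(np.abs(d))
    res = sps.wilcoxon(
        d,
        zero_method="wilcox",
        alternative="two-sided",
        correction=not exact,
        method="exact" if exact else "approx",
    )
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())  # report T+, not scipy's min(T+, T-)
    return TestResult(
        statistic=w_plus,
        p_value=float(min(res.pvalue, 1.0)),
        method="exact" if exact else "approximate",
    )


def fisher_exact_2x2(table) -> TestResult:
    """Two-sided Fisher exact test: sum hypergeometric probabilities of
    tables (given the margins) no more likely than the observed one."""
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValidationError("fisher_exact_2x2 requires a 2x2 table")
    if np.any(t < 0) or np.any(t != np.round(t)):
        raise ValidationError("table entries must be nonnegative integers")
    if t.sum() < 1:
        raise ValidationError("grand total must be >= 1")
    odds, p = sps.fisher_exact(t.astype(np.int64), alternative="two-sided")
    return TestResult(statistic=float(odds), p_value=float(min(p, 1.0)), method="exact")


def percentile(values, q: float) -> float:
    """Linear-interpolation percentile (index h = (n-1) q/100)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValidationError("percentile of empty vector")
    if not (0.0 <= q <= 100.0):
        raise ValidationError("q must lie in [0, 100]")
    return float(np.percentile(v, q, method="linear"))
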