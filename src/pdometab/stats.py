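"""Shared statistical kernel.

Every hypothesis test used by the pipeline stages lives here so that each
stage quotes the same conventions: two-sided tests by default, Welch degrees
of freedom for the t-test, exact enumeration for small-sample rank and
contingency tests, and Benjamini-Hochberg step-up adjustment applied within
an explicitly declared family of p-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "PValueFamily",
    "bh_adjust",
    "adjust_family",
    "t_test",
    "wilcoxon_rank_sum",
    "spearman",
    "fisher_exact",
    "lr_chisq",
]

#: largest per-arm sample size at which the rank-sum test uses exact
#: enumeration of the null distribution (falls back to the normal
#: approximation when ties are present, which the exact null cannot handle).
EXACT_RANKSUM_N = 10


@dataclass(frozen=True)
class TestResult:
    """Statistic + two-sided p-value, with an optional note for QC flags."""

    statistic: float
    pvalue: float
    df: float | None = None
    note: str = ""


@dataclass
class PValueFamily:
    """A named family of raw p-values adjusted together.

    The choice of family matters: BH controls the false-discovery rate only
    within the set of tests adjusted jointly, so each pipeline stage declares
    its family explicitly (e.g. all derived metrics of one flux assay).
    """

    test_ids: list[str]
    pvalues: np.ndarray
    family: str = "default"
    adjusted: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.pvalues = np.asarray(self.pvalues, dtype=float)
        if self.pvalues.size == 0:
            raise ValueError("empty p-value family")
        if len(self.test_ids) != self.pvalues.size:
            raise ValueError("test_ids and pvalues length mismatch")
        if np.any((self.pvalues < 0) | (self.pvalues > 1)):
            raise ValueError("p-values must lie in [0, 1]")


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    adjusted_(i) = min_{j >= i} p_(j) * n / j over the ascending order
    statistics, capped at 1, returned in the original order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value family")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adjusted_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.empty(n)
    adjusted[order] = np.minimum(adjusted_sorted, 1.0)
    return adjusted


def adjust_family(fam: PValueFamily) -> PValueFamily:
    """Apply :func:`bh_adjust` to a family in place and return it."""
    fam.adjusted = bh_adjust(fam.pvalues)
    return fam


def t_test(x, y, two_sided: bool = True, equal_var: bool = False) -> TestResult:
    """Two-sample t-test, Welch by default (Satterthwaite df).

    Degenerate input where both arms have zero variance is handled
    explicitly: equal constants give (t=0, p=1); distinct constants are an
    exact separation, reported as t=±inf, p=0 with a flag rather than a
    warning from the underlying routine.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least 2 observations per arm")
    if np.var(x) == 0.0 and np.var(y) == 0.0:
        if x.mean() == y.mean():
            return TestResult(0.0, 1.0, note="zero-variance, equal means")
        sign = 1.0 if x.mean() > y.mean() else -1.0
        return TestResult(sign * np.inf, 0.0, note="exact-separation")
    res = sps.ttest_ind(x, y, equal_var=equal_var)
    p = res.pvalue if two_sided else res.pvalue / 2.0
    return TestResult(float(res.statistic), float(p), df=float(res.df))


def wilcoxon_rank_sum(x, y) -> TestResult:
    """Two-sided Wilcoxon/Mann-Whitney rank-sum test.

    Exact enumeration of the null when both arms have <= EXACT_RANKSUM_N
    observations and no ties straddle the arms; otherwise the normal
    approximation with tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty arm")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    small = max(x.size, y.size) <= EXACT_RANKSUM_N
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return TestResult(float(res.statistic), float(res.pvalue), note=method)


def spearman(x, y) -> TestResult:
    """Spearman rank correlation rho with two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need matched vectors of length >= 3")
    rho, p = sps.spearmanr(x, y)
    return TestResult(float(rho), float(p))


def _check_table(table: np.ndarray) -> None:
    if np.any(table < 0):
        raise ValueError("negative cell count")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("degenerate table: zero margin")


def fisher_exact(table) -> TestResult:
    """Two-sided Fisher exact test on a 2x2 table.

    Two-sided p by summation of the probabilities of all tables (with the
    observed margins) no more probable than the observed one — the common
    convention, matching scipy.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2):
        raise ValueError("fisher_exact requires a 2x2 table")
    _check_table(t)
    odds, p = sps.fisher_exact(t, alternative="two-sided")
    return TestResult(float(odds), float(p))


def lr_chisq(table) -> TestResult:
    """Likelihood-ratio (G) test of independence on an r x c table.

    G = 2 * sum O * ln(O / E) with the 0*ln(0) = 0 convention; df =
    (r-1)(c-1); p from the chi-square distribution.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or min(t.shape) < 2:
        raise ValueError("need an r x c table with r, c >= 2")
    _check_table(t)
    total = t.sum()
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / total
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(t > 0, t * np.log(t / expected), 0.0)
    g = 2.0 * terms.sum()
    df = (t.shape[0] - 1) * (t.shape[1] - 1)
    p = float(sps.chi2.sf(g, df))
    return TestResult(float(g), p, df=float(df))
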