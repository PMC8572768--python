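"""Exact and classical statistics used throughout the pipeline.

Fisher's exact test on 2x2 tables is the workhorse: per-variant it
compares alt/ref read counts between cfDNA and PBL, per-gene it compares
carrier counts between cohorts, and per-set it drives gene-set
over-representation.  The two-sided p-value uses the point-probability
definition (sum of all tables, with the observed margins, whose
hypergeometric probability does not exceed the observed table's), which
is the convention of the standard statistical packages.  Two odds-ratio
estimates are reported: the sample cross-product OR (with a Haldane-
Anscombe 0.5 added to every cell iff any cell is zero) and the
conditional maximum-likelihood OR of the noncentral hypergeometric
model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np
from scipy import stats as _scipy_stats
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

# Relative tolerance for counting two point probabilities as tied when
# accumulating the two-sided p-value.
_TIE_RTOL = 1e-7
# Integer-scaled form of the same tolerance, for the rational oracle.
_TIE_NUM, _TIE_DEN = 10**7 + 1, 10**7


@dataclass(frozen=True)
class Table2x2:
    """2x2 contingency table; rows are groups, columns with/without."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(x < 0 for x in cells):
            raise ValueError("all cells must be non-negative")
        if all(x == 0 for x in cells):
            raise ValueError("table must have at least one positive margin")

    @property
    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


@dataclass(frozen=True)
class FisherResult:
    p_two_sided: float
    or_sample: float
    or_cmle: float


def _support(t: Table2x2) -> tuple[int, int, int, int, int]:
    """Margins and the support of cell ``a`` given the margins."""
    r1, r2 = t.a + t.b, t.c + t.d
    c1 = t.a + t.c
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    return r1, r2, c1, lo, hi


def sample_odds_ratio(t: Table2x2) -> float:
    """Cross-product OR, Haldane-corrected iff any cell is zero."""
    a, b, c, d = t.cells
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def _log_pmf_support(t: Table2x2) -> tuple[np.ndarray, np.ndarray]:
    """Hypergeometric log-pmf over the support of cell ``a``."""
    r1, r2, c1, lo, hi = _support(t)
    k = np.arange(lo, hi + 1)
    n = r1 + r2
    logpmf = (
        gammaln(r1 + 1) - gammaln(k + 1) - gammaln(r1 - k + 1)
        + gammaln(r2 + 1) - gammaln(c1 - k + 1) - gammaln(r2 - (c1 - k) + 1)
        - (gammaln(n + 1) - gammaln(c1 + 1) - gammaln(n - c1 + 1))
    )
    return k, logpmf


def _cmle_odds_ratio(t: Table2x2, rtol: float = 1e-9) -> float:
    """Conditional-MLE OR: solve E[a | margins, psi] = a by bisection.

    Returns 0.0 when ``a`` sits at the minimum of its support and
    ``inf`` at the maximum (the MLE diverges there).
    """
    _, _, _, lo, hi = _support(t)
    if lo == hi:  # degenerate support: any psi fits; report 1 by convention
        return 1.0
    if t.a == lo:
        return 0.0
    if t.a == hi:
        return math.inf
    k, logw0 = _log_pmf_support(t)  # pmf at psi=1 ~ weights up to a constant

    def mean_a(log_psi: float) -> float:
        logw = logw0 + k * log_psi
        w = np.exp(logw - logw.max())
        return float((k * w).sum() / w.sum())

    lo_l, hi_l = -1.0, 1.0
    while mean_a(lo_l) > t.a:
        lo_l *= 2
        if lo_l < -700:
            return 0.0
    while mean_a(hi_l) < t.a:
        hi_l *= 2
        if hi_l > 700:
            return math.inf
    for _ in range(200):
        mid = 0.5 * (lo_l + hi_l)
        if mean_a(mid) < t.a:
            lo_l = mid
        else:
            hi_l = mid
        if hi_l - lo_l < rtol:
            break
    return math.exp(0.5 * (lo_l + hi_l))


def fisher_exact(t: Table2x2) -> FisherResult:
    """Two-sided Fisher's exact test with both OR estimates.

    The p-value sums, over every table with the observed margins, the
    point probabilities that are <= the observed one (ties within a
    1e-7 relative tolerance included).
    """
    r1, r2, c1, lo, hi = _support(t)
    if lo == hi:
        # a is fully determined by the margins; only one table exists
        p = 1.0
    else:
        k, logpmf = _log_pmf_support(t)
        pmf = np.exp(logpmf)
        p_obs = pmf[t.a - lo]
        p = float(pmf[pmf <= p_obs * (1.0 + _TIE_RTOL)].sum())
        p = min(p, 1.0)
    return FisherResult(
        p_two_sided=p,
        or_sample=sample_odds_ratio(t),
        or_cmle=_cmle_odds_ratio(t),
    )


def fisher_oracle(t: Table2x2, max_margin: int = 500) -> float:
    """Two-sided p by exact rational enumeration; verification only.

    Enumerates every table consistent with the margins using integer
    binomial coefficients (all point probabilities share the
    denominator C(n, c1)), applying the same 1e-7 relative tie rule as
    :func:`fisher_exact` in exact arithmetic.
    """
    r1, r2, c1, lo, hi = _support(t)
    if min(r1, r2, c1, r1 + r2 - c1) > max_margin:
        raise ValueError(f"smallest margin exceeds {max_margin}")
    nums = [math.comb(r1, k) * math.comb(r2, c1 - k) for k in range(lo, hi + 1)]
    num_obs = nums[t.a - lo]
    total = sum(n for n in nums if n * _TIE_DEN <= num_obs * _TIE_NUM)
    return float(Fraction(total, math.comb(r1 + r2, c1)))


def pearson_r(xs: Sequence[float], ys: Sequence[float]) -> float:
    """Product-moment correlation; requires n >= 3 and nonzero variances."""
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.shape != ys.shape:
        raise ValueError("sequences must have equal length")
    if xs.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        raise ValueError("zero variance")
    return float(_scipy_stats.pearsonr(xs, ys).statistic)


def bh_fdr(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
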