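"""Shared two-sample statistics: Welch's t and the Mann-Whitney U test."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

#: smallest positive subnormal double; reported instead of an exact 0 p-value
P_UNDERFLOW_FLOOR = float(np.nextafter(0.0, 1.0))


@dataclass(frozen=True)
class WelchResult:
    statistic: float
    pvalue: float
    df: float
    #: True when a zero-variance degenerate input forced the p-value to a
    #: sentinel (1 for equal means, the underflow floor for unequal means)
    degenerate: bool = False


def welch_ttest(a, b) -> WelchResult:
    """Welch two-sample t with Satterthwaite degrees of freedom, two-sided p.

    Degenerate inputs (zero variance in both samples) return ``p = 1`` when the
    means are equal and the positive underflow floor when they are not, with
    ``degenerate=True``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("welch_ttest needs >=2 observations per group")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        df = float(a.size + b.size - 2)
        if a.mean() == b.mean():
            return WelchResult(0.0, 1.0, df, degenerate=True)
        sign = math.copysign(1.0, a.mean() - b.mean())
        return WelchResult(sign * math.inf, P_UNDERFLOW_FLOOR, df, degenerate=True)
    res = stats.ttest_ind(a, b, equal_var=False)
    return WelchResult(float(res.statistic), float(res.pvalue), float(res.df))


@dataclass(frozen=True)
class MannWhitneyResult:
    statistic: float  # U of the first sample
    pvalue: float
    method: str  # "exact" or "asymptotic"


def mannwhitney_u(x, y, exact_max_n: int = 8) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test.

    Exact enumeration (via the exact null distribution of U) when both samples
    have at most ``exact_max_n`` observations and the pooled sample is
    tie-free; otherwise the tie-corrected normal approximation without
    continuity correction, so identical samples give exactly ``p = 1``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = x.size, y.size
    if n == 0 or m == 0:
        raise ValueError("mannwhitney_u needs >=1 observation per group")
    pooled = np.concatenate([x, y])
    tie_free = np.unique(pooled).size == pooled.size
    if n <= exact_max_n and m <= exact_max_n and tie_free:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        return MannWhitneyResult(float(res.statistic), float(res.pvalue), "exact")
    # tie-corrected normal approximation
    ranks = stats.rankdata(pooled)
    r1 = ranks[:n].sum()
    u1 = r1 - n * (n + 1) / 2.0
    big_n = n + m
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts).sum()) / (big_n * (big_n - 1))) if big_n > 1 else 0.0
    var = n * m / 12.0 * (big_n + 1 - tie_term)
    if var <= 0.0:
        return MannWhitneyResult(float(u1), 1.0, "asymptotic")
    z = (u1 - n * m / 2.0) / math.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return MannWhitneyResult(float(u1), float(min(p, 1.0)), "asymptotic")


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg adjusted q-values (NaNs propagated)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvals, dtype=float)
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q
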