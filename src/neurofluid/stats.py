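"""Cohort statistics: Anderson-Darling normality, Spearman and partial
Spearman rank correlation, and Benjamini-Hochberg FDR adjustment.

These are authored here (rather than delegated) because together they are the
analysis battery this package reproduces; established implementations serve
as independent cross-checks in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np
from scipy.stats import norm, rankdata
from scipy.stats import t as t_dist

__all__ = [
    "CorrelationResult",
    "anderson_darling",
    "spearman",
    "partial_spearman",
    "bh_fdr",
]

EXACT_PERMUTATION_N = 7  # at or below this n, Spearman p is enumerated exactly


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_value: float
    n: int
    covariates: tuple = ()
    fdr_adjusted_p: float | None = None
    method: str = "spearman"


def _drop_missing(*cols):
    arrs = [np.asarray(c, dtype=float) for c in cols]
    n = arrs[0].size
    if any(a.size != n for a in arrs):
        raise ValueError("all variables must have equal length")
    keep = np.all(np.isfinite(np.column_stack(arrs)), axis=1)
    return [a[keep] for a in arrs]


def anderson_darling(values) -> tuple:
    """Anderson-Darling normality test with estimated mean and variance.

    Returns (A*^2, p): the small-sample adjusted statistic
    A*^2 = A^2 * (1 + 0.75/n + 2.25/n^2) and its p-value from the standard
    piecewise-exponential approximation for the estimated-parameters case.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n < 5:
        raise ValueError("Anderson-Darling requires n >= 5")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance: normality is undefined for a constant sample")
    z = (x - x.mean()) / sd
    u = norm.cdf(z)
    u = np.clip(u, 1e-15, 1 - 1e-15)
    i = np.arange(1, n + 1)
    a2 = -n - np.sum((2 * i - 1) * (np.log(u) + np.log(1 - u[::-1]))) / n
    a2_star = a2 * (1.0 + 0.75 / n + 2.25 / n**2)
    if a2_star >= 0.6:
        p = math.exp(1.2937 - 5.709 * a2_star + 0.0186 * a2_star**2)
    elif a2_star >= 0.34:
        p = math.exp(0.9177 - 4.279 * a2_star - 1.38 * a2_star**2)
    elif a2_star >= 0.2:
        p = 1 - math.exp(-8.318 + 42.796 * a2_star - 59.938 * a2_star**2)
    else:
        p = 1 - math.exp(-13.436 + 101.14 * a2_star - 223.73 * a2_star**2)
    return float(a2_star), float(min(max(p, 0.0), 1.0))


def _rank_corr(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    if denom == 0:
        raise ValueError("a variable is constant; rank correlation undefined")
    return float(rx @ ry) / denom


def _t_approx_p(rho: float, df: int) -> float:
    if df <= 0:
        return float("nan")
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * math.sqrt(df / (1.0 - rho * rho))
    return float(2.0 * t_dist.sf(abs(t), df))


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation with mid-ranks for ties.

    Missing pairs are dropped first. The two-sided p-value uses the t
    approximation at n - 2 degrees of freedom; for n <= 7 the exact
    permutation distribution is enumerated instead.
    """
    x, y = _drop_missing(x, y)
    n = x.size
    if n < 3:
        raise ValueError("Spearman correlation requires n >= 3 complete pairs")
    rx, ry = rankdata(x), rankdata(y)
    rho = _rank_corr(rx, ry)
    if n <= EXACT_PERMUTATION_N:
        count = 0
        total = 0
        for perm in permutations(ry):
            total += 1
            if abs(_rank_corr(rx, np.array(perm))) >= abs(rho) - 1e-12:
                count += 1
        p = count / total
    else:
        p = _t_approx_p(rho, n - 2)
    return CorrelationResult(rho=rho, p_value=p, n=n)


def _maybe_rank(col: np.ndarray) -> np.ndarray:
    # binary covariates (e.g. sex coded 0/1) pass through unranked; ranking a
    # binary is an affine map so the residuals are unchanged either way
    if np.unique(col).size <= 2:
        return col
    return rankdata(col)


def partial_spearman(x, y, covariates) -> CorrelationResult:
    """Rank-based partial correlation of x and y given covariates.

    x, y and each (non-binary) covariate are mid-rank transformed; the ranked
    x and y are residualised on the ranked covariates (with intercept) by
    least squares, and the Pearson correlation of the residuals is returned
    with a t-approximation p at n - k - 2 degrees of freedom.
    """
    covariates = [np.asarray(c, dtype=float) for c in covariates]
    if not covariates:
        return spearman(x, y)
    cols = _drop_missing(x, y, *covariates)
    x, y, covs = cols[0], cols[1], cols[2:]
    n = x.size
    k = len(covs)
    if n <= k + 2:
        raise ValueError(f"need n > {k + 2} complete rows for {k} covariates")
    rx, ry = rankdata(x), rankdata(y)
    z = np.column_stack([np.ones(n)] + [_maybe_rank(c) for c in covs])
    if np.linalg.matrix_rank(z) < z.shape[1]:
        raise ValueError("collinear covariates")
    beta_x, *_ = np.linalg.lstsq(z, rx, rcond=None)
    beta_y, *_ = np.linalg.lstsq(z, ry, rcond=None)
    ex, ey = rx - z @ beta_x, ry - z @ beta_y
    rho = _rank_corr(ex, ey)
    p = _t_approx_p(rho, n - k - 2)
    return CorrelationResult(
        rho=rho,
        p_value=p,
        n=n,
        covariates=tuple(f"c{i + 1}" for i in range(k)),
        method="partial_spearman",
    )


def bh_fdr(p_values) -> np.ndarray:
    """Step-up Benjamini-Hochberg adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(scaled[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out
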