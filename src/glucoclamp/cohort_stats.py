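"""Cohort-level statistics: Spearman correlation, standardized major
axis (SMA) regression, common-slope heterogeneity testing, and R^2.

Metric-glycemia associations are assessed on log10 scale.  SMA (also
called reduced major axis) regression is the appropriate symmetric
line fit when both axes carry error: the slope is
``sign(r) * sd(y)/sd(x)`` and the line passes through the centroid.
Slope heterogeneity between groups is tested with a likelihood-ratio
statistic built from the correlation between SMA residuals
``y - b x`` and fitted axis scores ``y + b x`` (zero at each group's
own slope), minimized over a common slope and referred to chi-squared
with ``g - 1`` degrees of freedom; a label-permutation fallback is
provided.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
from scipy import stats
from scipy.optimize import minimize_scalar

from .errors import DegenerateInputError, DomainError

__all__ = [
    "spearman", "spearman_exact_p", "SMAFit", "sma_fit",
    "sma_common_slope_test", "r_squared",
]


def _clean_pair(x, y, min_n=3):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DomainError("x and y must be 1-D arrays of equal length")
    if len(x) < min_n:
        raise DomainError(f"need at least {min_n} observations")
    if np.any(~np.isfinite(x)) or np.any(~np.isfinite(y)):
        raise DomainError("inputs must be finite")
    return x, y


def spearman(x, y, method: str = "t"):
    """Spearman rank correlation with mid-ranks for ties.

    ``method='t'`` uses the t-approximation for the p-value (the
    common choice at cohort-scale n); ``method='exact'`` enumerates all
    permutations (only for n <= 10).  Returns ``(r, p)``.
    """
    x, y = _clean_pair(x, y)
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise DegenerateInputError("constant vector: correlation undefined")
    if method == "exact":
        return spearman_exact_p(x, y)
    r, p = stats.spearmanr(x, y)
    return float(r), float(p)


def spearman_exact_p(x, y):
    """Exhaustive-permutation two-sided p for Spearman's r (n <= 10)."""
    x, y = _clean_pair(x, y)
    n = len(x)
    if n > 10:
        raise DomainError("exact permutation p-value limited to n <= 10")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    r_obs = np.corrcoef(rx, ry)[0, 1]
    count = 0
    total = 0
    rx_c = rx - rx.mean()
    denom_x = np.sqrt(np.sum(rx_c ** 2))
    for perm in permutations(range(n)):
        ryp = ry[list(perm)]
        ry_c = ryp - ryp.mean()
        r = float(rx_c @ ry_c) / (denom_x * np.sqrt(np.sum(ry_c ** 2)))
        if abs(r) >= abs(r_obs) - 1e-12:
            count += 1
        total += 1
    return float(r_obs), count / total


@dataclass
class SMAFit:
    slope: float
    intercept: float
    r: float
    n: int
    group: str | None = None


def sma_fit(x, y, group: str | None = None) -> SMAFit:
    """Standardized major axis fit of y on x (both axes with error)."""
    x, y = _clean_pair(x, y)
    sx = x.std(ddof=1)
    sy = y.std(ddof=1)
    if sx == 0 or sy == 0:
        raise DegenerateInputError("zero variance on one axis")
    r = float(np.corrcoef(x, y)[0, 1])
    sign = 1.0 if r >= 0 else -1.0
    slope = sign * sy / sx
    intercept = float(y.mean() - slope * x.mean())
    return SMAFit(slope=float(slope), intercept=intercept, r=r,
                  n=len(x), group=group)


def _residual_fitted_corr2(x, y, b):
    """Squared correlation of SMA residuals y-bx with fitted axis y+bx."""
    res = y - b * x
    fit = y + b * x
    sr = res.std(ddof=1)
    sf = fit.std(ddof=1)
    if sr == 0 or sf == 0:
        return 0.0
    c = np.cov(res, fit, ddof=1)[0, 1] / (sr * sf)
    return min(c * c, 1.0 - 1e-15)


def _common_slope_stat(groups, b):
    return sum(-(len(x) - 2.5) * np.log1p(-_residual_fitted_corr2(x, y, b))
               for x, y in groups)


def sma_common_slope_test(group1, group2, method: str = "lr",
                          n_permutations: int = 1000, seed=None):
    """Test whether two groups share a common SMA slope.

    ``group1``/``group2`` are ``(x, y)`` tuples.  The LR statistic
    minimizes ``sum_i -(n_i - 2.5) ln(1 - r_i(b)^2)`` over the common
    slope ``b`` (with ``r_i`` the group's residual-fitted correlation)
    and is referred to chi-squared with 1 df.  ``method='permutation'``
    recomputes the statistic under random reassignments of rows to
    groups instead.  Returns the p-value.
    """
    groups = []
    for g in (group1, group2):
        x, y = _clean_pair(g[0], g[1])
        if x.std(ddof=1) == 0 or y.std(ddof=1) == 0:
            raise DegenerateInputError("degenerate group (zero variance)")
        groups.append((x, y))

    fits = [sma_fit(x, y) for x, y in groups]
    signs = {1.0 if f.slope >= 0 else -1.0 for f in fits}
    sign = signs.pop() if len(signs) == 1 else 1.0
    log_b0 = np.log10(np.mean([abs(f.slope) for f in fits]))

    def stat_of_logb(lb):
        return _common_slope_stat(groups, sign * 10.0 ** lb)

    res = minimize_scalar(stat_of_logb,
                          bounds=(log_b0 - 3.0, log_b0 + 3.0),
                          method="bounded",
                          options={"xatol": 1e-10})
    t_obs = float(res.fun)

    if method == "lr":
        return float(stats.chi2.sf(t_obs, df=1))
    if method != "permutation":
        raise DomainError(f"unknown method {method!r}")

    rng = np.random.default_rng(seed)
    xs = np.concatenate([g[0] for g in groups])
    ys = np.concatenate([g[1] for g in groups])
    n1 = len(groups[0][0])
    count = 0
    for _ in range(n_permutations):
        idx = rng.permutation(len(xs))
        ga = (xs[idx[:n1]], ys[idx[:n1]])
        gb = (xs[idx[n1:]], ys[idx[n1:]])
        try:
            r = minimize_scalar(
                lambda lb: _common_slope_stat([ga, gb], sign * 10.0 ** lb),
                bounds=(log_b0 - 3.0, log_b0 + 3.0), method="bounded",
                options={"xatol": 1e-8})
        except (ValueError, FloatingPointError):
            continue
        if r.fun >= t_obs - 1e-12:
            count += 1
    return (count + 1) / (n_permutations + 1)


def r_squared(observed, predicted) -> float:
    """Coefficient of determination ``1 - SS_res / SS_tot``."""
    obs, pred = _clean_pair(observed, predicted, min_n=2)
    ss_tot = np.sum((obs - obs.mean()) ** 2)
    if ss_tot == 0:
        raise DegenerateInputError("zero total variance in observed values")
    ss_res = np.sum((obs - pred) ** 2)
    return float(1.0 - ss_res / ss_tot)
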