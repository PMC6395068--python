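"""Shared statistical primitives: BH adjustment, exact overlap tests,
correlation/regression with intervals, pooled summaries."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps


def bh_adjust(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q values, in input order.

    q_(i) = min_{j >= i} p_(j) * m / j over the sorted p values, clipped to
    [0, 1]; ties handled by the standard max-rank step-up.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


@dataclass(frozen=True)
class Overlap2x2:
    """Overlap of a query list (size n) with a set (size K) in a universe
    of N items; k items are shared."""

    k: int
    K: int
    n: int
    N: int

    def __post_init__(self) -> None:
        if not (0 <= self.k <= min(self.K, self.n)):
            raise ValueError(
                f"overlap k={self.k} outside [0, min(K={self.K}, n={self.n})]"
            )
        if self.K > self.N or self.n > self.N:
            raise ValueError(
                f"set size K={self.K} and query size n={self.n} must not "
                f"exceed universe N={self.N}"
            )
        if min(self.k, self.K, self.n, self.N) < 0:
            raise ValueError("all table entries must be non-negative")
        if self.N - self.K - self.n + self.k < 0:
            raise ValueError(
                f"impossible overlap: k={self.k} < K + n - N = "
                f"{self.K + self.n - self.N}"
            )

    def as_table(self) -> np.ndarray:
        """2x2 contingency table [[k, n-k], [K-k, N-K-n+k]]."""
        return np.array(
            [
                [self.k, self.n - self.k],
                [self.K - self.k, self.N - self.K - self.n + self.k],
            ]
        )


def hypergeom_upper_tail(t: Overlap2x2) -> float:
    """Exact P(X >= k) for X ~ Hypergeom(N, K, n)."""
    # sf(k-1) = P(X >= k)
    return float(np.clip(sps.hypergeom.sf(t.k - 1, t.N, t.K, t.n), 0.0, 1.0))


def fisher_exact_overlap(t: Overlap2x2) -> tuple[float, float]:
    """One-sided (enrichment) Fisher exact test on the overlap table.

    Returns the sample odds ratio k(N-K-n+k) / ((n-k)(K-k)) and the upper
    tail p. The enrichment tail coincides with `hypergeom_upper_tail`.
    Degenerate tables (a zero margin) return p = 1 with a warning instead
    of erroring, so permutation loops survive them.
    """
    table = t.as_table()
    row_margins = table.sum(axis=1)
    col_margins = table.sum(axis=0)
    if 0 in row_margins or 0 in col_margins:
        warnings.warn(
            f"degenerate overlap table {table.tolist()}: zero margin, p set to 1",
            stacklevel=2,
        )
        return float("nan"), 1.0
    odds, p = sps.fisher_exact(table, alternative="greater")
    return float(odds), float(p)


def pearson_correlation_test(
    x: Sequence[float] | np.ndarray, y: Sequence[float] | np.ndarray
) -> tuple[float, float]:
    """Pearson r with a two-sided p from the t distribution on n-2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in x or y")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class RegressionLine:
    slope: float
    intercept: float
    level: float
    x: np.ndarray
    fitted: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    pi_lower: np.ndarray
    pi_upper: np.ndarray


def ols_line_with_intervals(
    x: Sequence[float] | np.ndarray,
    y: Sequence[float] | np.ndarray,
    level: float = 0.95,
    x_eval: Sequence[float] | np.ndarray | None = None,
) -> RegressionLine:
    """Simple least-squares line with pointwise confidence and prediction
    bands at `level`, by the standard normal-theory formulas.

    CI half-width at x0: t * s * sqrt(1/n + (x0-xbar)^2/Sxx); the
    prediction band adds 1 under the square root.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x")
    xbar = x.mean()
    sxx = float(np.sum((x - xbar) ** 2))
    slope = float(np.sum((x - xbar) * (y - y.mean())) / sxx)
    intercept = float(y.mean() - slope * xbar)
    resid = y - (intercept + slope * x)
    dof = n - 2
    s2 = float(np.sum(resid**2) / dof)
    tcrit = float(sps.t.ppf(0.5 + level / 2.0, dof))
    xe = x if x_eval is None else np.asarray(x_eval, dtype=float)
    fitted = intercept + slope * xe
    se_mean = np.sqrt(s2 * (1.0 / n + (xe - xbar) ** 2 / sxx))
    se_pred = np.sqrt(s2 * (1.0 + 1.0 / n + (xe - xbar) ** 2 / sxx))
    return RegressionLine(
        slope=slope,
        intercept=intercept,
        level=level,
        x=xe,
        fitted=fitted,
        ci_lower=fitted - tcrit * se_mean,
        ci_upper=fitted + tcrit * se_mean,
        pi_lower=fitted - tcrit * se_pred,
        pi_upper=fitted + tcrit * se_pred,
    )


def pooled_weighted_mean(
    group_means: Sequence[float], group_ns: Sequence[int]
) -> float:
    """Sample-size-weighted mean of group means: sum(n_i m_i) / sum(n_i)."""
    means = np.asarray(group_means, dtype=float)
    ns = np.asarray(group_ns, dtype=float)
    if means.size == 0:
        raise ValueError("group_means must be non-empty")
    if means.shape != ns.shape:
        raise ValueError("group_means and group_ns must have equal length")
    if np.any(ns < 1):
        raise ValueError("all group sizes must be >= 1")
    return float(np.sum(ns * means) / np.sum(ns))


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (the convention used for the printed
    percentages), avoiding banker's rounding."""
    factor = 10.0**ndigits
    scaled = x * factor
    r = np.floor(np.abs(scaled) + 0.5) * np.sign(scaled) / factor
    return float(r)
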