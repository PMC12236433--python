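"""Statistical primitives used throughout the pipeline.

Self-contained implementations of the four tests every stage relies on:

* Pearson correlation with a two-sided p-value from the exact t transform
  ``t = r * sqrt((n-2) / (1-r^2))`` on ``n-2`` degrees of freedom;
* the Kruskal-Wallis H-test with midranks and the tie-correction divisor
  ``1 - sum(t^3 - t) / (N^3 - N)``, p from a chi-square with ``k-1`` df
  (an exact permutation null is available for tiny samples);
* Benjamini-Hochberg step-up FDR adjustment;
* a two-group negative-binomial Wald test with a method-of-moments
  dispersion estimate (no shrinkage), the workhorse of the differential
  expression stage.

Vectorised variants (`kruskal_wallis_table`, `nb_wald_matrix`) run one test
per matrix row and are what the pipeline stages actually call; the scalar
functions are the reference path.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "AdjustedPValues",
    "pearson",
    "kruskal_wallis",
    "kruskal_wallis_table",
    "benjamini_hochberg",
    "nb_wald_two_group",
    "nb_wald_matrix",
    "median_of_ratios_size_factors",
]

DISPERSION_FLOOR = 1e-8


@dataclass(frozen=True)
class TestResult:
    """Outcome of a single hypothesis test."""

    statistic: float
    p_value: float
    df_or_n: int
    method: str  # "pearson" | "kruskal_wallis" | "nb_wald"

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [0,1]")
        if self.method == "pearson" and abs(self.statistic) > 1 + 1e-12:
            raise ValueError(f"Pearson r {self.statistic} outside [-1,1]")


@dataclass(frozen=True)
class AdjustedPValues:
    raw: np.ndarray
    adjusted: np.ndarray


# ---------------------------------------------------------------------------
# Pearson correlation


def pearson(x: np.ndarray, y: np.ndarray) -> TestResult:
    """Sample Pearson correlation with two-sided t-transform p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or x.size != y.size:
        raise ValueError("x and y must be 1-d vectors of equal length")
    n = x.size
    if n < 3:
        raise ValueError(f"need n >= 3 observations, got {n}")
    dx = x - x.mean()
    dy = y - y.mean()
    sxx = float(dx @ dx)
    syy = float(dy @ dy)
    if sxx == 0.0 or syy == 0.0:
        raise ValueError("constant input: zero variance")
    r = float(dx @ dy) / np.sqrt(sxx * syy)
    r = float(np.clip(r, -1.0, 1.0))
    df = n - 2
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r * r))
        p = float(2.0 * sps.t.sf(abs(t), df))
    return TestResult(statistic=r, p_value=p, df_or_n=df, method="pearson")


# ---------------------------------------------------------------------------
# Kruskal-Wallis


def _h_from_ranks(ranks: np.ndarray, sizes: np.ndarray, tie_term: float) -> float:
    N = int(sizes.sum())
    h = 0.0
    start = 0
    for n_g in sizes:
        r_sum = ranks[start : start + n_g].sum()
        h += r_sum * r_sum / n_g
        start += n_g
    h = 12.0 / (N * (N + 1)) * h - 3.0 * (N + 1)
    denom = 1.0 - tie_term / (N**3 - N)
    if denom <= 0:  # all values identical
        return 0.0
    return h / denom


def _tie_term(pooled: np.ndarray) -> float:
    _, counts = np.unique(pooled, return_counts=True)
    t = counts.astype(float)
    return float(np.sum(t**3 - t))


def kruskal_wallis(groups: list[np.ndarray], exact: bool = False) -> TestResult:
    """Kruskal-Wallis H-test across two or more groups.

    Midranks handle ties; H is divided by the tie-correction factor
    ``1 - sum(t^3 - t)/(N^3 - N)``.  The p-value comes from the chi-square
    approximation with ``k-1`` df, or, with ``exact=True``, from complete
    enumeration of group assignments (feasible only for tiny pooled N).
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    if any(a.size == 0 for a in arrays):
        raise ValueError("all groups must be nonempty")
    pooled = np.concatenate(arrays)
    N = pooled.size
    if N < 3:
        raise ValueError("need at least 3 observations in total")
    sizes = np.array([a.size for a in arrays])
    if np.all(pooled == pooled[0]):
        return TestResult(0.0, 1.0, len(arrays) - 1, "kruskal_wallis")
    ranks = sps.rankdata(pooled)
    tie = _tie_term(pooled)
    h = _h_from_ranks(ranks, sizes, tie)
    df = len(arrays) - 1
    if exact:
        p = _kw_exact_p(ranks, sizes, tie, h)
    else:
        p = float(sps.chi2.sf(h, df))
    return TestResult(float(h), p, df, "kruskal_wallis")


def _kw_exact_p(ranks: np.ndarray, sizes: np.ndarray, tie: float, h_obs: float) -> float:
    """Exact permutation p-value by enumerating group assignments.

    Only the multiset split matters, so for two groups we enumerate the
    combinations of indices forming the first group.  Guarded to tiny N.
    """
    N = ranks.size
    if len(sizes) != 2:
        raise NotImplementedError("exact p-value implemented for two groups only")
    if comb(N, int(sizes[0])) > 200_000:
        raise ValueError("pooled sample too large for exact enumeration")
    idx = np.arange(N)
    count = 0
    total = 0
    tol = 1e-12
    for first in combinations(idx, int(sizes[0])):
        mask = np.zeros(N, dtype=bool)
        mask[list(first)] = True
        perm = np.concatenate([ranks[mask], ranks[~mask]])
        h = _h_from_ranks(perm, sizes, tie)
        count += h >= h_obs - tol
        total += 1
    return count / total


def kruskal_wallis_table(values: np.ndarray, group_a: np.ndarray, group_b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise two-group Kruskal-Wallis over a features x samples matrix.

    Parameters are the matrix and two integer/boolean index arrays selecting
    the columns of each group.  Returns (H, p) vectors.  Rows whose pooled
    values are all identical get H = 0, p = 1.
    """
    values = np.asarray(values, dtype=float)
    a = values[:, group_a]
    b = values[:, group_b]
    pooled = np.concatenate([a, b], axis=1)
    n_feat, N = pooled.shape
    n_a = a.shape[1]
    ranks = sps.rankdata(pooled, axis=1)
    r_a = ranks[:, :n_a].sum(axis=1)
    r_b = ranks[:, n_a:].sum(axis=1)
    h = 12.0 / (N * (N + 1)) * (r_a**2 / n_a + r_b**2 / (N - n_a)) - 3.0 * (N + 1)
    # row-wise tie correction
    srt = np.sort(pooled, axis=1)
    boundary = np.ones_like(srt, dtype=bool)
    boundary[:, 1:] = srt[:, 1:] != srt[:, :-1]
    tie_sum = np.empty(n_feat)
    for i in range(n_feat):  # run lengths per row
        counts = np.diff(np.append(np.flatnonzero(boundary[i]), N)).astype(float)
        tie_sum[i] = np.sum(counts**3 - counts)
    denom = 1.0 - tie_sum / (N**3 - N)
    constant = denom <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        h = np.where(constant, 0.0, h / np.where(constant, 1.0, denom))
    h = np.maximum(h, 0.0)
    p = sps.chi2.sf(h, 1)
    p = np.where(constant, 1.0, p)
    return h, p


# ---------------------------------------------------------------------------
# Benjamini-Hochberg


def benjamini_hochberg(p: np.ndarray) -> AdjustedPValues:
    """Step-up FDR adjustment: q(i) = min_{j>=i} p(j) * m / j on sorted p.

    Ties keep stable-sort order; adjusted values are capped at 1 and mapped
    back to the input order.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be a 1-d vector")
    if p.size == 0:
        return AdjustedPValues(raw=p, adjusted=p.copy())
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0,1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return AdjustedPValues(raw=p.copy(), adjusted=q)


# ---------------------------------------------------------------------------
# Negative-binomial Wald test


def median_of_ratios_size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors over features nonzero in every sample.

    The geometric-mean reference is computed on features with all-positive
    counts; each sample's factor is the median ratio to that reference.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2:
        raise ValueError("counts must be a features x samples matrix")
    positive = np.all(counts > 0, axis=1)
    if not positive.any():
        raise ValueError("no feature has positive counts in every sample")
    sub = counts[positive]
    log_gm = np.mean(np.log(sub), axis=1, keepdims=True)
    ratios = sub / np.exp(log_gm)
    return np.median(ratios, axis=0)


def _nb_group_stats(y: np.ndarray, s: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Scaled counts y = c/s: per-row mean, within-row sample variance, n."""
    mu = y.mean(axis=1)
    var = y.var(axis=1, ddof=1)
    return mu, var, np.full(y.shape[0], y.shape[1])


def nb_wald_matrix(
    counts_a: np.ndarray,
    counts_b: np.ndarray,
    size_factors_a: np.ndarray | None = None,
    size_factors_b: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise two-group NB Wald test.

    Counts are scaled by their size factors; per-group means are the means
    of the scaled counts.  A common per-feature dispersion ``alpha`` is
    estimated by pooled method of moments, ``alpha = (var - mu) / mu^2``
    averaged across groups and floored at 1e-8.  The Wald statistic
    contrasts ``log(mu_b) - log(mu_a)`` with a delta-method standard error
    and a standard-normal reference.

    Returns ``(log2_fold_change, z, p)`` with the b-over-a orientation.
    Features zero in both groups get log2FC = 0 and p = 1; a group with
    zero mean (but not both) receives a half-count continuity correction
    on its total so the fold change stays finite.
    """
    a = np.atleast_2d(np.asarray(counts_a, dtype=float))
    b = np.atleast_2d(np.asarray(counts_b, dtype=float))
    if a.shape[0] != b.shape[0]:
        raise ValueError("groups must have the same number of features")
    n_a, n_b = a.shape[1], b.shape[1]
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs at least 2 samples")
    sa = np.ones(n_a) if size_factors_a is None else np.asarray(size_factors_a, dtype=float)
    sb = np.ones(n_b) if size_factors_b is None else np.asarray(size_factors_b, dtype=float)
    if np.any(sa <= 0) or np.any(sb <= 0):
        raise ValueError("size factors must be > 0")
    ya = a / sa
    yb = b / sb
    mu_a, var_a, _ = _nb_group_stats(ya, sa)
    mu_b, var_b, _ = _nb_group_stats(yb, sb)

    both_zero = (mu_a == 0) & (mu_b == 0)
    # pooled MoM dispersion on the scaled counts, averaged over groups
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_a = (var_a - mu_a) / mu_a**2
        alpha_b = (var_b - mu_b) / mu_b**2
    stack = np.stack([alpha_a, alpha_b])
    finite = np.isfinite(stack)
    alpha = np.where(finite, stack, 0.0).sum(axis=0) / np.maximum(finite.sum(axis=0), 1)
    alpha = np.maximum(alpha, DISPERSION_FLOOR)

    # continuity correction keeps single-sided zeros finite
    mu_a_c = np.where((mu_a == 0) & ~both_zero, 0.5 / (n_a * sa.mean()), mu_a)
    mu_b_c = np.where((mu_b == 0) & ~both_zero, 0.5 / (n_b * sb.mean()), mu_b)

    with np.errstate(divide="ignore", invalid="ignore"):
        log2fc = np.log2(mu_b_c / mu_a_c)
        # Var(mean of y_i) with y_i = c_i/s_i, Var(c_i) = mu*s_i + alpha*(mu*s_i)^2
        var_mean_a = (mu_a_c * np.sum(1.0 / sa) / n_a**2) + alpha * mu_a_c**2 / n_a
        var_mean_b = (mu_b_c * np.sum(1.0 / sb) / n_b**2) + alpha * mu_b_c**2 / n_b
        se = np.sqrt(var_mean_a / mu_a_c**2 + var_mean_b / mu_b_c**2)
        z = (np.log(mu_b_c) - np.log(mu_a_c)) / se
    p = 2.0 * sps.norm.sf(np.abs(z))
    log2fc = np.where(both_zero, 0.0, log2fc)
    z = np.where(both_zero, 0.0, z)
    p = np.where(both_zero, 1.0, np.clip(p, 0.0, 1.0))
    return log2fc, z, p


def nb_wald_two_group(
    counts_a: np.ndarray,
    counts_b: np.ndarray,
    size_factors: np.ndarray | None = None,
) -> tuple[TestResult, float]:
    """Scalar NB Wald test for one feature; returns (TestResult, log2FC).

    ``size_factors`` concatenates group a then group b factors; ``None``
    means unit factors.
    """
    counts_a = np.asarray(counts_a, dtype=float)
    counts_b = np.asarray(counts_b, dtype=float)
    if size_factors is None:
        sa = sb = None
    else:
        size_factors = np.asarray(size_factors, dtype=float)
        if size_factors.size != counts_a.size + counts_b.size:
            raise ValueError("size_factors must cover both groups")
        sa = size_factors[: counts_a.size]
        sb = size_factors[counts_a.size :]
    log2fc, z, p = nb_wald_matrix(counts_a[None, :], counts_b[None, :], sa, sb)
    n = counts_a.size + counts_b.size
    return TestResult(float(z[0]), float(p[0]), n, "nb_wald"), float(log2fc[0])
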