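"""Statistical machinery of the audit.

One-way PERMANOVA on Euclidean distances is implemented here rather
than delegated, so that the permutation stream is fully seeded, an
exhaustive-enumeration mode exists for tiny inputs, and the pseudo-F
and R-squared come from one code path; scikit-bio's implementation
serves as an independent cross-check in the test suite.  The remaining
tests (Wilcoxon signed-rank, Welch t, chi-square of proportions,
simple linear regression) wrap scipy with the package's conventions:
two-sided p values reported alongside the 99% confidence convention.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as _scistats
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "DegenerateStatisticsError",
    "PermanovaResult",
    "permanova",
    "wilcoxon_signed_rank_paired",
    "welch_t_test",
    "chi_square_proportions",
    "RegressionResult",
    "linear_fit",
    "TestResult",
]


class DegenerateStatisticsError(ValueError):
    """The input admits no meaningful test (constant data, one group...)."""


@dataclass
class TestResult:
    statistic: float
    p_value: float
    confidence_level: float = 0.99


@dataclass
class PermanovaResult:
    f_statistic: float
    r_squared: float
    p_value: float
    n_permutations: int
    seed: int | None
    method: str = "permutation"


def _group_indicators(labels) -> tuple[np.ndarray, list]:
    labels = np.asarray(labels)
    groups = sorted(set(labels.tolist()))
    onehot = np.stack([(labels == g).astype(float) for g in groups])
    return onehot, groups


def _permanova_terms(d2: np.ndarray, onehot: np.ndarray) -> tuple[float, float]:
    """(F, R^2) from a squared-distance matrix and group indicators."""
    n = d2.shape[0]
    g = onehot.shape[0]
    sst = d2.sum() / (2 * n)
    sizes = onehot.sum(axis=1)
    within = np.einsum("gi,ij,gj->g", onehot, d2, onehot) / (2 * sizes)
    ssw = within.sum()
    ssa = sst - ssw
    if ssw <= 0:
        f = math.inf
    else:
        f = (ssa / (g - 1)) / (ssw / (n - g))
    r2 = ssa / sst if sst > 0 else math.nan
    return f, r2


def permanova(
    matrix,
    labels,
    n_permutations: int = 999,
    seed: int | None = None,
    method: str = "permutation",
) -> PermanovaResult:
    """One-way PERMANOVA of a feature matrix under Euclidean distance.

    Parameters
    ----------
    matrix:
        (n_samples, n_features) array; rows are, e.g., per-gene RSCU
        vectors.
    labels:
        one group label per row; at least two groups.
    method:
        ``"permutation"`` draws ``n_permutations`` seeded label
        permutations and reports p = (#{F_perm >= F_obs} + 1) /
        (n_permutations + 1); ``"exact"`` enumerates all row orderings
        (only feasible for n <= 8) and reports the exact proportion
        with F_perm >= F_obs.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2:
        raise ValueError("matrix must be 2-D")
    labels = np.asarray(labels)
    if labels.shape[0] != x.shape[0]:
        raise ValueError("one label per row required")
    onehot, groups = _group_indicators(labels)
    if len(groups) < 2:
        raise DegenerateStatisticsError("PERMANOVA needs at least two groups")
    d2 = squareform(pdist(x, metric="sqeuclidean"))
    if d2.max() == 0:
        raise DegenerateStatisticsError("all rows identical: no distance structure")
    f_obs, r2 = _permanova_terms(d2, onehot)
    n = x.shape[0]

    if method == "exact":
        if n > 8:
            raise ValueError("exact enumeration limited to n <= 8 rows")
        count = 0
        total = 0
        base = np.asarray(labels)
        for perm in itertools.permutations(range(n)):
            oh, _ = _group_indicators(base[list(perm)])
            f_perm, _ = _permanova_terms(d2, oh)
            count += f_perm >= f_obs - 1e-12
            total += 1
        return PermanovaResult(
            f_statistic=float(f_obs),
            r_squared=float(r2),
            p_value=count / total,
            n_permutations=total,
            seed=None,
            method="exact",
        )

    if method != "permutation":
        raise ValueError("method must be 'permutation' or 'exact'")
    if n_permutations < 99:
        raise ValueError("need at least 99 permutations")
    rng = np.random.default_rng(seed)
    perms = np.stack(
        [rng.permutation(n) for _ in range(n_permutations)]
    )  # (P, n)
    count = 0
    # batched einsum over permuted one-hot stacks, one group at a time
    sizes = onehot.sum(axis=1)
    ssw_perm = np.zeros(n_permutations)
    for g_idx in range(onehot.shape[0]):
        permuted = onehot[g_idx][perms]  # (P, n)
        ssw_perm += np.einsum(
            "pi,ij,pj->p", permuted, d2, permuted
        ) / (2 * sizes[g_idx])
    sst = d2.sum() / (2 * n)
    g = onehot.shape[0]
    with np.errstate(divide="ignore"):
        f_perm = ((sst - ssw_perm) / (g - 1)) / (ssw_perm / (n - g))
    count = int(np.sum(f_perm >= f_obs - 1e-12))
    p = (count + 1) / (n_permutations + 1)
    return PermanovaResult(
        f_statistic=float(f_obs),
        r_squared=float(r2),
        p_value=float(p),
        n_permutations=n_permutations,
        seed=seed,
        method="permutation",
    )


def wilcoxon_signed_rank_paired(a, b) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped before ranking (Wilcoxon's original
    prescription).  The p value is exact for n <= 25 remaining pairs
    and uses the normal approximation above that.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size == 0:
        raise ValueError("paired samples must be equal-length and non-empty")
    diff = a - b
    diff = diff[diff != 0]
    if diff.size == 0:
        raise DegenerateStatisticsError("all paired differences are zero")
    method = "exact" if diff.size <= 25 else "approx"
    res = _scistats.wilcoxon(
        diff, zero_method="wilcox", alternative="two-sided", method=method
    )
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue))


def welch_t_test(x, y) -> TestResult:
    """Two-sided Welch t test (unequal variances)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least two observations")
    t, p = _scistats.ttest_ind(x, y, equal_var=False)
    if math.isnan(t):
        raise DegenerateStatisticsError("zero variance in both samples")
    return TestResult(statistic=float(t), p_value=float(p))


def chi_square_proportions(k1: int, n1: int, k2: int, n2: int) -> TestResult:
    """Chi-square test of equal proportions k1/n1 vs k2/n2.

    Plain (uncorrected) 2x2 contingency chi-square, matching the
    textbook formula; identical proportions give statistic 0, p = 1.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("totals must be positive")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("counts must lie within their totals")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    if np.any(table.sum(axis=0) == 0):
        raise DegenerateStatisticsError("a column of the 2x2 table is empty")
    if k1 / n1 == k2 / n2:
        return TestResult(statistic=0.0, p_value=1.0)
    res = _scistats.chi2_contingency(table, correction=False)
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue))


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float


def linear_fit(x, y) -> RegressionResult:
    """Ordinary least squares y ~ x with a two-sided slope p value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least three paired points")
    if np.ptp(x) == 0:
        raise DegenerateStatisticsError("x has zero variance")
    res = _scistats.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue) ** 2,
        p_value=float(res.pvalue),
    )
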