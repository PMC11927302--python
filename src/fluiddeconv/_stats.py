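"""Shared statistical primitives.

Exact (tie-aware) and asymptotic two-sample Mann-Whitney U tests, the
upper-tail hypergeometric over-representation p-value, and Benjamini-Hochberg
step-up adjustment. These are shared by the deconvolution, signature-scoring,
differential-expression and enrichment modules so that every module exercises
the same, tested implementations.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

__all__ = ["bh_adjust", "mann_whitney", "hypergeom_test"]

# exact enumeration (dynamic program) below this per-group size, asymptotic above
_EXACT_MIN_GROUP = 8


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    adj_(i) = min_{j >= i} min(1, m * p_(j) / j) on the sorted p-values,
    mapped back to the input order. Controls the FDR at the reported level
    under independence / positive dependence.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-D vector of p-values")
    m = p.size
    if m == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    out = np.empty(m, dtype=float)
    out[order] = adj
    return out


def _ranksum_distribution(doubled_ranks: np.ndarray, n1: int) -> np.ndarray:
    """Exact null distribution of the doubled rank-sum of a size-n1 subset.

    Returns counts[s] = number of n1-subsets of the pooled midranks whose
    doubled rank-sum equals s. Midranks are doubled so tied (x.5) ranks
    stay integral. Counts fit in float64 exactly for the group sizes that
    reach this branch (min group <= 8).
    """
    total = int(doubled_ranks.sum())
    # ways[j, s]: subsets of size j with doubled-rank-sum s
    ways = np.zeros((n1 + 1, total + 1))
    ways[0, 0] = 1.0
    for r in doubled_ranks:
        r = int(r)
        for j in range(min(n1, 1_000_000), 0, -1):
            ways[j, r:] += ways[j - 1, : total + 1 - r]
    return ways[n1]


def _exact_mw_p(x: np.ndarray, y: np.ndarray, alternative: str) -> float:
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    doubled = np.rint(2 * ranks).astype(np.int64)
    n1 = x.size
    obs = int(doubled[:n1].sum())
    counts = _ranksum_distribution(doubled, n1)
    total = counts.sum()
    p_low = counts[: obs + 1].sum() / total   # P(R <= obs)
    p_high = counts[obs:].sum() / total       # P(R >= obs)
    if alternative == "less":
        return float(p_low)
    if alternative == "greater":
        return float(p_high)
    return float(min(1.0, 2.0 * min(p_low, p_high)))


def _asymptotic_mw_p(x: np.ndarray, y: np.ndarray, alternative: str) -> float:
    n1, n2 = x.size, y.size
    n = n1 + n2
    ranks = sps.rankdata(np.concatenate([x, y]))
    u1 = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    _, tie_counts = np.unique(np.concatenate([x, y]), return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if sigma2 <= 0:  # all values tied
        return 1.0
    # continuity correction of 0.5 toward the mean
    if alternative == "greater":
        z = (u1 - mu - 0.5) / np.sqrt(sigma2)
        return float(sps.norm.sf(z))
    if alternative == "less":
        z = (u1 - mu + 0.5) / np.sqrt(sigma2)
        return float(sps.norm.cdf(z))
    z = (abs(u1 - mu) - 0.5) / np.sqrt(sigma2)
    return float(min(1.0, 2.0 * sps.norm.sf(z)))


def mann_whitney(x, y, alternative: str = "two-sided") -> tuple[float, float]:
    """Two-sample Mann-Whitney U test.

    Returns (U, p) where U is the U statistic of the first sample.
    `alternative` is relative to the first sample: "greater" tests whether
    x tends to exceed y. The exact tie-aware permutation distribution is
    used whenever min(len(x), len(y)) <= 8; otherwise the normal
    approximation with midranks, tie correction and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    n1 = x.size
    ranks = sps.rankdata(np.concatenate([x, y]))
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    if min(x.size, y.size) <= _EXACT_MIN_GROUP:
        p = _exact_mw_p(x, y, alternative)
    else:
        p = _asymptotic_mw_p(x, y, alternative)
    return u1, p


def hypergeom_test(M: int, K: int, n: int, k: int) -> float:
    """Upper-tail hypergeometric p-value P(X >= k).

    X counts successes in n draws without replacement from a universe of M
    items of which K are successes. The observed overlap k is included in
    the tail (over-representation convention).
    """
    M, K, n, k = int(M), int(K), int(n), int(k)
    if not (0 <= k <= min(K, n) <= M and K <= M and n <= M and k >= 0):
        raise ValueError(f"inconsistent hypergeometric parameters M={M}, K={K}, n={n}, k={k}")
    return float(sps.hypergeom.sf(k - 1, M, K, n))
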