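"""Library-size and composition normalization.

Counts-per-million scaling, trimmed-mean-of-M-values (TMM) between-sample
factors, and the log2(CPM + pseudocount) transform used by signature
scoring and differential expression. TMM directly addresses the library
size and composition variability of body-fluid RNA (urine solute
concentration varies with hydration and voided volume, which skews naive
depth normalization).

TMM here follows the canonical estimator: M-values (log2 expression
ratios versus a reference sample) and A-values (average log2 abundance)
are computed over genes nonzero in both samples, the extremes of both are
trimmed (defaults 30% of M, 5% of A, double-sided, rank-based), and the
factor is 2**(inverse-variance weighted mean of the surviving M-values),
with factors rescaled to geometric mean 1. The reference sample is the
one whose upper-quartile expression is closest to the mean upper
quartile. A plain (unweighted) trimmed mean is available via
``weighted=False``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DataError

__all__ = ["cpm", "tmm_factors", "log_norm"]


def _check_totals(counts: pd.DataFrame) -> np.ndarray:
    totals = counts.sum(axis=0).to_numpy(dtype=float)
    bad = counts.columns[totals <= 0].tolist()
    if bad:
        raise DataError(f"samples with zero total counts: {bad}")
    return totals


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts per million: counts(g, s) / total(s) * 1e6."""
    totals = _check_totals(counts)
    return counts / totals * 1e6


def _trim_keep(values: np.ndarray, trim: float) -> np.ndarray:
    """Rank-based double-sided trim: keep ranks in (floor(n*trim), n - floor(n*trim)]."""
    n = values.size
    cut = int(np.floor(n * trim))
    ranks = sps.rankdata(values, method="average")
    return (ranks > cut) & (ranks <= n - cut)


def tmm_factors(
    counts: pd.DataFrame,
    ref_sample: str | None = None,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    weighted: bool = True,
) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factor per sample.

    Factors multiply the library size: effective depth = total * factor.
    Normalized so the factors' geometric mean is 1.
    """
    if counts.shape[1] < 2:
        raise DataError("TMM needs at least 2 samples")
    if not (0 <= trim_m < 0.5 and 0 <= trim_a < 0.5):
        raise ValueError("trims must lie in [0, 0.5)")
    totals = _check_totals(counts)
    mat = counts.to_numpy(dtype=float)

    if ref_sample is None:
        uq = np.quantile(mat / totals, 0.75, axis=0)
        ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    else:
        ref_idx = counts.columns.get_loc(ref_sample)

    y_r, n_r = mat[:, ref_idx], totals[ref_idx]
    factors = np.ones(counts.shape[1])
    for j in range(counts.shape[1]):
        if j == ref_idx:
            continue
        y_k, n_k = mat[:, j], totals[j]
        keep = (y_k > 0) & (y_r > 0)
        if not keep.any():
            raise DataError(f"no genes shared between {counts.columns[j]} and reference")
        pk, pr = y_k[keep] / n_k, y_r[keep] / n_r
        m = np.log2(pk / pr)
        a = 0.5 * np.log2(pk * pr)
        sel = _trim_keep(m, trim_m) & _trim_keep(a, trim_a)
        if not sel.any():
            raise DataError(f"no genes survive trimming for {counts.columns[j]}")
        if weighted:
            w = 1.0 / (
                (n_k - y_k[keep]) / (n_k * y_k[keep])
                + (n_r - y_r[keep]) / (n_r * y_r[keep])
            )
            factors[j] = 2.0 ** (np.sum(w[sel] * m[sel]) / np.sum(w[sel]))
        else:
            factors[j] = 2.0 ** np.mean(m[sel])

    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def log_norm(
    counts: pd.DataFrame,
    factors: pd.Series | None = None,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """log2(CPM + pseudocount), with TMM-adjusted effective library sizes.

    With ``factors=None`` all factors are 1 and this is exactly
    log2(cpm(counts) + pseudocount).
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    totals = _check_totals(counts)
    if factors is None:
        eff = totals
    else:
        eff = totals * factors.reindex(counts.columns).to_numpy(dtype=float)
    return np.log2(counts / eff * 1e6 + pseudocount)
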