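"""Covariate-adjusted differential expression between two sample classes.

Per gene, ordinary least squares of log2(CPM+TMM + pseudocount) on
[intercept, class indicator, covariates]; the reported log2 fold change is
the class coefficient (second class relative to the first) and its p-value
comes from the coefficient's t statistic with n - p degrees of freedom.
BH correction runs across the tested genes; a gene is called significant
at adjusted p < 0.05 with |log2FC| > 0 (no fold-change floor beyond sign).
95% log2FC confidence intervals are bootstrapped by resampling samples
with replacement within class and refitting.

Spot creatinine and RNA-isolation volume are the motivating covariates:
body-fluid solute concentration varies between voids and can confound
class comparisons, so it is regressed out rather than ignored. This is a
plain linear model, not an empirical-Bayes moderated fit; in very small
cohorts moderated procedures will differ (see docs/methods.md).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._stats import bh_adjust
from .errors import DataError, DesignError
from .normalization import cpm, log_norm, tmm_factors

__all__ = ["build_design", "fit_de", "bootstrap_logfc_ci"]


def build_design(labels: pd.Series, covariates: pd.DataFrame | None = None) -> tuple[pd.DataFrame, str]:
    """Design matrix [intercept, class, covariates...]; returns (X, second_class)."""
    classes = sorted(labels.unique())
    if len(classes) != 2:
        raise ValueError(f"exactly two classes required, got {classes}")
    counts = labels.value_counts()
    if counts.min() < 2:
        raise ValueError("both classes need at least 2 samples")
    x = pd.DataFrame(
        {"intercept": 1.0, "class": (labels == classes[1]).astype(float)}, index=labels.index
    )
    if covariates is not None:
        cov = covariates.reindex(labels.index)
        if cov.isna().any().any():
            missing = cov.index[cov.isna().any(axis=1)].tolist()
            raise DataError(f"missing covariate values for samples: {missing}")
        x = pd.concat([x, cov.astype(float)], axis=1)
    _check_collinearity(x)
    return x, classes[1]


def _check_collinearity(x: pd.DataFrame) -> None:
    mat = x.to_numpy(dtype=float)
    if np.linalg.matrix_rank(mat) == mat.shape[1]:
        return
    # name the offending columns: those perfectly predicted by the rest
    bad = []
    for j, name in enumerate(x.columns):
        others = np.delete(mat, j, axis=1)
        coef, *_ = np.linalg.lstsq(others, mat[:, j], rcond=None)
        resid = mat[:, j] - others @ coef
        if np.allclose(resid, 0.0, atol=1e-8 * max(1.0, np.abs(mat[:, j]).max())):
            bad.append(name)
    raise DesignError(f"collinear design columns: {bad or list(x.columns)}")


def _normalized_log(counts: pd.DataFrame, pseudocount: float, use_tmm: bool) -> pd.DataFrame:
    factors = tmm_factors(counts) if use_tmm else None
    return log_norm(counts, factors=factors, pseudocount=pseudocount)


def default_filter(counts: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Keep genes with CPM >= 1 in at least min(n_A, n_B) samples."""
    n_min = int(labels.value_counts().min())
    keep = (cpm(counts) >= 1.0).sum(axis=1) >= n_min
    return counts.loc[keep]


def fit_de(
    counts: pd.DataFrame,
    labels: pd.Series,
    covariates: pd.DataFrame | None = None,
    filter_spec=default_filter,
    pseudocount: float = 1.0,
    use_tmm: bool = True,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene OLS differential expression (second class vs first).

    Returns a DataFrame indexed by gene, sorted by adjusted p, with
    log2fc, p_raw, p_adj, mean_expr and the significance call.
    """
    labels = labels.reindex(counts.columns)
    if labels.isna().any():
        raise DataError("class label missing for some samples")
    x, _ = build_design(labels, covariates)
    filtered = filter_spec(counts, labels) if filter_spec is not None else counts
    if filtered.empty:
        raise DataError("no genes survive filtering")
    y = _normalized_log(filtered, pseudocount, use_tmm).to_numpy(dtype=float)  # genes x samples
    xm = x.to_numpy(dtype=float)
    n, p = xm.shape
    if n <= p:
        raise DesignError("fewer samples than design columns")

    xtx_inv = np.linalg.inv(xm.T @ xm)
    hat = xtx_inv @ xm.T                       # p x n
    beta = y @ hat.T                           # genes x p
    resid = y - beta @ xm.T
    df = n - p
    sigma2 = (resid**2).sum(axis=1) / df
    se = np.sqrt(np.maximum(sigma2 * xtx_inv[1, 1], 1e-300))
    tstat = beta[:, 1] / se
    pvals = 2.0 * sps.t.sf(np.abs(tstat), df)

    out = pd.DataFrame(
        {
            "log2fc": beta[:, 1],
            "p_raw": pvals,
            "p_adj": bh_adjust(pvals),
            "mean_expr": y.mean(axis=1),
            "t": tstat,
        },
        index=filtered.index,
    )
    out["significant"] = (out["p_adj"] < alpha) & (out["log2fc"].abs() > 0)
    return out.sort_values("p_adj", kind="mergesort")


def bootstrap_logfc_ci(
    counts: pd.DataFrame,
    labels: pd.Series,
    genes,
    covariates: pd.DataFrame | None = None,
    n_boot: int = 1000,
    seed: int = 0,
    pseudocount: float = 1.0,
    use_tmm: bool = True,
) -> pd.DataFrame:
    """Percentile 95% CI of the class coefficient by within-class resampling.

    Samples are resampled with replacement inside each class (so every
    resample keeps both classes); resamples with a degenerate (collinear)
    design are redrawn. The point estimate is appended to the bootstrap
    set so the interval always contains it.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    labels = labels.reindex(counts.columns)
    genes = [g for g in genes if g in counts.index]
    if not genes:
        raise DataError("none of the requested genes are present")

    def class_coef(cols) -> np.ndarray:
        sub = counts[cols]
        sub = sub.loc[sub.sum(axis=1) > 0]
        lab = pd.Series(labels.loc[cols].to_numpy(), index=sub.columns)
        cov = None
        if covariates is not None:
            cov = pd.DataFrame(
                covariates.reindex(labels.index).loc[cols].to_numpy(),
                index=sub.columns,
                columns=covariates.columns,
            )
        x, _ = build_design(lab, cov)
        y = _normalized_log(sub, pseudocount, use_tmm)
        present = [g for g in genes if g in y.index]
        if len(present) != len(genes):
            raise DataError("gene filtered out in resample")
        xm = x.to_numpy(dtype=float)
        beta = y.loc[genes].to_numpy() @ (np.linalg.pinv(xm.T @ xm) @ xm.T).T
        return beta[:, 1]

    point = class_coef(list(counts.columns))
    rng = np.random.default_rng(seed)
    classes = sorted(labels.unique())
    idx_by_class = {c: labels.index[labels == c].to_numpy() for c in classes}

    boots = [point]
    attempts = 0
    while len(boots) < n_boot + 1:
        attempts += 1
        if attempts > 20 * n_boot:
            raise DataError("bootstrap kept producing degenerate designs")
        cols = []
        for c in classes:
            pool = idx_by_class[c]
            cols.extend(rng.choice(pool, size=pool.size, replace=True))
        try:
            boots.append(class_coef(cols))
        except (DesignError, DataError):
            continue
    arr = np.array(boots)
    return pd.DataFrame(
        {
            "log2fc": point,
            "ci_low": np.quantile(arr, 0.025, axis=0),
            "ci_high": np.quantile(arr, 0.975, axis=0),
        },
        index=pd.Index(genes, name="gene"),
    )
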