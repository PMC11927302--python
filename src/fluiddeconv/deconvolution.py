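"""Cell-type deconvolution of bulk body-fluid transcriptomes.

Each bulk sample's CPM vector over the genes shared with the basis matrix
is decomposed as a non-negative combination of the basis columns
(min ||B w - y||_2, w >= 0, solved by NNLS); the relative fractions of
cell-type-specific RNA are w / sum(w). A nu-SVR solver (linear kernel,
coefficients clipped to the non-negative orthant) is available behind a
flag for fidelity with support-vector deconvolution designs; NNLS is the
deterministic default.

Post-processing follows the body-fluid workflow: fractions below 0.1%
are zeroed (strictly below; rows are deliberately NOT renormalized, which
would silently inflate the surviving fractions), per-cell-type confidence
intervals come from a gene-resampling bootstrap, and two-group comparisons
use a two-sided Mann-Whitney U test per cell type, restricted by the
sparsity inclusion rule: with group sizes n_A and n_B, a cell type is
tested only if its proportion of nonzero fractions across the pooled
cohort is at least min(n_A, n_B) / (n_A + n_B). BH correction runs across
the tested cell types only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize

from ._stats import bh_adjust, mann_whitney
from .errors import DataError

__all__ = [
    "FractionTable",
    "deconvolve",
    "zero_small_fractions",
    "fraction_ci",
    "compare_groups",
]


@dataclass
class FractionTable:
    """Sample x cell-type relative fractions with per-sample fit residuals."""

    fractions: pd.DataFrame
    residual: pd.Series
    ci_low: pd.DataFrame | None = None
    ci_high: pd.DataFrame | None = None
    dropped_samples: list = field(default_factory=list)


def _shared_cpm(bulk: pd.DataFrame, basis: pd.DataFrame):
    shared = bulk.index.intersection(basis.index)
    if len(shared) == 0:
        raise DataError("no genes shared between bulk and basis")
    if len(shared) < 50:
        warnings.warn(f"only {len(shared)} genes shared between bulk and basis")
    b = basis.loc[shared].to_numpy(dtype=float)
    y = bulk.loc[shared].to_numpy(dtype=float)
    totals = bulk.sum(axis=0).to_numpy(dtype=float)
    if np.any(totals <= 0):
        raise DataError("bulk sample with zero total counts")
    y = y / totals * 1e6  # CPM over ALL bulk genes -> scale-invariant in the bulk vector
    return shared, b, y


def _solve_nnls(b: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    w, res = scipy.optimize.nnls(b, y)
    return w, float(res)


def _solve_nusvr(b: np.ndarray, y: np.ndarray, nu: float = 0.5) -> tuple[np.ndarray, float]:
    from sklearn.svm import NuSVR

    model = NuSVR(kernel="linear", nu=nu, C=1.0)
    model.fit(b, y)
    w = np.clip(model.coef_.ravel(), 0.0, None)
    return w, float(np.linalg.norm(b @ w - y))


def deconvolve(bulk: pd.DataFrame, basis: pd.DataFrame, method: str = "nnls") -> FractionTable:
    """Estimate relative cell-type RNA fractions per bulk sample.

    Bulk columns are CPM-normalized internally, so the result is invariant
    to global rescaling of any bulk sample. Samples whose solution is all
    zero are flagged unresolvable and omitted with a warning.
    """
    solvers = {"nnls": _solve_nnls, "nu-svr": _solve_nusvr}
    if method not in solvers:
        raise ValueError(f"unknown method {method!r}")
    _, b, y = _shared_cpm(bulk, basis)
    rows, residuals, dropped = [], [], []
    for j, sample in enumerate(bulk.columns):
        w, res = solvers[method](b, y[:, j])
        total = w.sum()
        if total <= 0:
            warnings.warn(f"sample {sample} unresolvable (all-zero solution); omitted")
            dropped.append(sample)
            continue
        rows.append(w / total)
        residuals.append(res)
    kept = [s for s in bulk.columns if s not in dropped]
    return FractionTable(
        fractions=pd.DataFrame(rows, index=kept, columns=basis.columns),
        residual=pd.Series(residuals, index=kept, name="residual"),
        dropped_samples=dropped,
    )


def zero_small_fractions(ft: FractionTable, threshold: float = 0.001) -> FractionTable:
    """Zero fractions strictly below ``threshold`` (default 0.1%).

    Rows are not renormalized. Idempotent. Rows that become all zero are
    kept but excluded downstream by ``compare_groups``.
    """
    if not (0 <= threshold < 1):
        raise ValueError("threshold must lie in [0, 1)")
    fr = ft.fractions.where(ft.fractions >= threshold, 0.0)
    return FractionTable(
        fractions=fr,
        residual=ft.residual,
        ci_low=ft.ci_low,
        ci_high=ft.ci_high,
        dropped_samples=list(ft.dropped_samples),
    )


def fraction_ci(
    bulk_sample: pd.Series,
    basis: pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
    method: str = "nnls",
) -> pd.DataFrame:
    """Percentile 95% CI per cell type from a gene-resampling bootstrap.

    Gene rows of the (shared-gene, CPM) system are resampled with
    replacement and the sample re-deconvolved; the point estimate is
    appended to the bootstrap set so the interval always contains it.
    Degenerate resamples (all-zero solution) are redrawn.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    bulk = bulk_sample.to_frame()
    _, b, y = _shared_cpm(bulk, basis)
    y = y[:, 0]
    solver = _solve_nnls if method == "nnls" else _solve_nusvr
    w0, _ = solver(b, y)
    if w0.sum() <= 0:
        raise DataError("sample unresolvable; no CI")
    point = w0 / w0.sum()

    rng = np.random.default_rng(seed)
    n_genes = b.shape[0]
    boots = [point]
    draws = 0
    while len(boots) < n_boot + 1:
        draws += 1
        if draws > 20 * n_boot:
            raise DataError("bootstrap failed to produce resolvable resamples")
        idx = rng.integers(0, n_genes, size=n_genes)
        w, _ = solver(b[idx], y[idx])
        if w.sum() <= 0:
            continue
        boots.append(w / w.sum())
    arr = np.array(boots)
    return pd.DataFrame(
        {
            "fraction": point,
            "ci_low": np.quantile(arr, 0.025, axis=0),
            "ci_high": np.quantile(arr, 0.975, axis=0),
        },
        index=basis.columns,
    )


def compare_groups(ft_a: FractionTable, ft_b: FractionTable, alpha: float = 0.05) -> pd.DataFrame:
    """Per-cell-type two-group comparison with the sparsity inclusion rule.

    Cell type c is tested iff the proportion of pooled samples with
    fraction(c) > 0 is at least q = min(n_A, n_B) / (n_A + n_B); tested
    cell types get a two-sided Mann-Whitney U (exact for small groups) and
    BH correction across the tested family only. All-zero rows (samples
    zeroed out entirely) are excluded first.
    """
    fa = ft_a.fractions.loc[ft_a.fractions.sum(axis=1) > 0]
    fb = ft_b.fractions.loc[ft_b.fractions.sum(axis=1) > 0]
    n_a, n_b = len(fa), len(fb)
    if min(n_a, n_b) < 2:
        raise ValueError("each group needs at least 2 usable samples")
    if list(fa.columns) != list(fb.columns):
        raise DataError("fraction tables have different cell-type columns")
    n = n_a + n_b
    q = min(n_a, n_b) / n

    records = []
    for ct in fa.columns:
        a, b = fa[ct].to_numpy(), fb[ct].to_numpy()
        nonzero = int((a > 0).sum() + (b > 0).sum())
        tested = (nonzero / n) >= q
        rec = {
            "cell_type": ct,
            "tested": tested,
            "n_nonzero": nonzero,
            "median_A": float(np.median(a)),
            "median_B": float(np.median(b)),
            "U": np.nan,
            "p_raw": np.nan,
        }
        if tested:
            u, p = mann_whitney(a, b, alternative="two-sided")
            rec["U"], rec["p_raw"] = u, p
        records.append(rec)
    out = pd.DataFrame(records).set_index("cell_type")
    out["p_adj"] = np.nan
    mask = out["tested"].to_numpy()
    if mask.any():
        out.loc[mask, "p_adj"] = bh_adjust(out.loc[mask, "p_raw"].to_numpy())
    out["significant"] = out["p_adj"] < alpha
    return out
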