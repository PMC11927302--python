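"""Basis-matrix construction and cell-type gene profiles from a labeled atlas.

The deconvolution design matrix is the per-cell-type pseudobulk (counts
summed over cells of a type, then CPM-scaled), which weights cells by
depth — the standard construction for reference-based deconvolution.
Cell-type gene profiles are the genes specifically expressed in one
column: at least ``min_cpm`` and at least ``fold_threshold`` times the
best other column. With fold_threshold > 1 a gene can satisfy the rule
for at most one cell type, so profiles are disjoint by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError
from .synthetic import ReferenceAtlas

__all__ = ["CellTypeProfile", "pseudobulk", "derive_profiles", "basis_collinearity"]


@dataclass
class CellTypeProfile:
    """Named gene set specific to one cell type."""

    cell_type: str
    genes: frozenset
    derivation_params: dict

    def __post_init__(self):
        if not self.genes:
            raise ValueError(f"empty profile for {self.cell_type}")


def pseudobulk(atlas: ReferenceAtlas, min_cells: int = 2, on_small: str = "error") -> pd.DataFrame:
    """Gene x cell-type basis matrix: per-label summed counts on the CPM scale."""
    labels, n_cells = np.unique(atlas.cell_types, return_counts=True)
    small = labels[n_cells < min_cells].tolist()
    if small:
        if on_small == "error":
            raise DataError(f"cell types with fewer than {min_cells} cells: {small}")
        warnings.warn(f"dropping small cell types: {small}")
        labels = [lab for lab in labels if lab not in small]
    cols = {}
    for lab in labels:
        tot = atlas.counts[atlas.cell_types == lab].sum(axis=0).astype(float)
        if tot.sum() <= 0:
            raise DataError(f"cell type {lab} has zero total counts")
        cols[lab] = tot / tot.sum() * 1e6
    return pd.DataFrame(cols, index=atlas.gene_ids)


def derive_profiles(
    basis: pd.DataFrame, fold_threshold: float = 10.0, min_cpm: float = 10.0
) -> list[CellTypeProfile]:
    """Cell-type-specific gene sets from a basis matrix.

    Columns are renormalized to the CPM scale first, so the rule is
    invariant to global rescaling of the basis. Gene g enters profile(c)
    iff basis(g, c) >= min_cpm and basis(g, c) >= fold_threshold * max of
    the other columns. Cell types whose profile comes out empty are
    dropped with a warning.
    """
    if fold_threshold <= 1:
        raise ValueError("fold_threshold must exceed 1")
    col_sums = basis.sum(axis=0).to_numpy(dtype=float)
    if np.any(col_sums <= 0):
        raise DataError("basis has a zero column")
    values = basis.to_numpy(dtype=float) / col_sums * 1e6
    params = {"fold_threshold": fold_threshold, "min_cpm": min_cpm}

    profiles = []
    for j, cell_type in enumerate(basis.columns):
        others = np.delete(values, j, axis=1)
        best_other = others.max(axis=1)
        own = values[:, j]
        mask = (own >= min_cpm) & (own >= fold_threshold * best_other)
        genes = frozenset(basis.index[mask])
        if not genes:
            warnings.warn(f"no profile genes for {cell_type}; excluded")
            continue
        profiles.append(CellTypeProfile(str(cell_type), genes, dict(params)))
    return profiles


def basis_collinearity(basis: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation between cell types over log2(CPM + 1) of all genes.

    Symmetric with unit diagonal; constant columns yield NaN (flagged
    missing) rather than an error.
    """
    if basis.shape[1] < 2:
        raise ValueError("need at least 2 cell types")
    col_sums = basis.sum(axis=0).to_numpy(dtype=float)
    logged = np.log2(basis.to_numpy(dtype=float) / col_sums * 1e6 + 1.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        corr = np.corrcoef(logged, rowvar=False)
    out = pd.DataFrame(corr, index=basis.columns, columns=basis.columns)
    np.fill_diagonal(out.values, 1.0)
    return out
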