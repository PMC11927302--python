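"""Cell-type signature scoring on normalized bulk expression.

The signature score of sample j for a cell-type gene profile is the
arithmetic mean of the log2(CPM+TMM)-normalized expression g_ij over the
N profile genes present in the (filtered) matrix:

    score_j = (1/N) * sum_i g_ij

Profile genes absent from the matrix are dropped and N adjusted (recorded
per profile) rather than imputed as zero — treating missing as zero would
conflate count filtering with biology.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from ._stats import mann_whitney
from .basis import CellTypeProfile
from .errors import DataError

__all__ = ["SignatureScoreTable", "filter_counts", "signature_score", "score_table", "compare_signature"]


@dataclass
class SignatureScoreTable:
    scores: pd.DataFrame          # sample x cell type
    n_genes_used: pd.Series       # cell type -> N


def filter_counts(counts: pd.DataFrame, min_count: int = 1, min_sample_frac: float = 0.25) -> pd.DataFrame:
    """Keep genes with >= min_count counts in >= min_sample_frac of samples."""
    n_needed = max(1, int(round(min_sample_frac * counts.shape[1])))
    keep = (counts >= min_count).sum(axis=1) >= n_needed
    return counts.loc[keep]


def signature_score(norm: pd.DataFrame, profile: CellTypeProfile) -> tuple[pd.Series, int]:
    """Mean normalized expression of the profile genes, per sample."""
    present = norm.index.intersection(sorted(profile.genes))
    if len(present) == 0:
        raise DataError(f"no genes of profile {profile.cell_type!r} present in the matrix")
    scores = norm.loc[present].mean(axis=0)
    scores.name = profile.cell_type
    return scores, len(present)


def score_table(norm: pd.DataFrame, profiles) -> SignatureScoreTable:
    cols, ns = {}, {}
    for prof in profiles:
        s, n = signature_score(norm, prof)
        cols[prof.cell_type] = s
        ns[prof.cell_type] = n
    return SignatureScoreTable(
        scores=pd.DataFrame(cols), n_genes_used=pd.Series(ns, name="n_genes_used")
    )


def compare_signature(scores_a, scores_b, alternative: str = "two-sided") -> tuple[float, float]:
    """Mann-Whitney comparison of per-sample signature scores between groups.

    ``alternative="greater"`` tests whether the first group's scores tend
    to exceed the second's. Shares the exact/asymptotic implementation
    used by the deconvolution group comparison.
    """
    return mann_whitney(scores_a, scores_b, alternative=alternative)
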