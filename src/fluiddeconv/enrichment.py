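"""Hypergeometric over-representation tests over GMT collections.

One upper-tail hypergeometric test per set (universe M, set size K after
universe intersection, query size n, overlap k), BH correction across all
tested sets in the invocation (sets that become empty after universe
intersection are untestable and excluded from the family), and the joint
transcriptome-metabolome intersection of significantly enriched pathways.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from ._stats import bh_adjust, hypergeom_test
from .errors import DataError

__all__ = ["hypergeom_test", "enrich_sets", "joint_pathways"]


def enrich_sets(query, collection: dict, universe, alpha: float = 0.05) -> pd.DataFrame:
    """Over-representation of ``query`` ids in each set of ``collection``.

    Ids are deduplicated; query ids outside the universe are dropped with
    a warning; each set is intersected with the universe before testing.
    Returns one row per testable set with M, K, n, k, p_raw, p_adj,
    the overlapping ids, and the significance call at ``alpha``.
    """
    universe = set(universe)
    query = set(query)
    if not universe or not query:
        raise DataError("universe and query must be non-empty")
    outside = query - universe
    if outside:
        warnings.warn(f"{len(outside)} query ids outside the universe were dropped")
        query &= universe
        if not query:
            raise DataError("no query ids remain inside the universe")

    m, n = len(universe), len(query)
    records = []
    for name, members in collection.items():
        members = set(members) & universe
        if not members:
            continue  # untestable; keep out of the BH family
        overlap = query & members
        records.append(
            {
                "set_id": name,
                "M": m,
                "K": len(members),
                "n": n,
                "k": len(overlap),
                "p_raw": hypergeom_test(m, len(members), n, len(overlap)),
                "overlap_ids": ",".join(sorted(overlap)),
            }
        )
    if not records:
        raise DataError("no testable sets after universe intersection")
    out = pd.DataFrame(records).set_index("set_id")
    out["p_adj"] = bh_adjust(out["p_raw"].to_numpy())
    out["significant"] = out["p_adj"] < alpha
    return out.sort_values(["p_adj", "p_raw"], kind="mergesort")


def joint_pathways(
    result_rna: pd.DataFrame, result_met: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Pathways enriched (adjusted p < alpha) in BOTH omics.

    Both inputs are ``enrich_sets`` outputs over the same pathway
    namespace; zero shared set ids is treated as a namespace mismatch.
    """
    shared = result_rna.index.intersection(result_met.index)
    if len(shared) == 0:
        raise DataError("no shared pathway ids between the two enrichment results")
    rna = result_rna.loc[shared]
    met = result_met.loc[shared]
    if alpha >= 1:  # degenerate threshold: every tested pathway qualifies
        keep = pd.Series(True, index=shared)
    else:
        keep = (rna["p_adj"] < alpha) & (met["p_adj"] < alpha)
    out = pd.DataFrame(
        {
            "p_adj_rna": rna["p_adj"],
            "p_adj_met": met["p_adj"],
            "overlap_rna": rna["overlap_ids"],
            "overlap_met": met["overlap_ids"],
        }
    ).loc[keep]
    return out.sort_values(["p_adj_rna", "p_adj_met"], kind="mergesort")
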