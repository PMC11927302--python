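"""Transcriptome-metabolome integration through metabolic subsystems.

Measured cell-type-specific genes and annotated metabolites are linked via
a reaction-annotation table (rows of reaction id, subsystem, gene or
metabolite participant — the shape of a genome-scale metabolic model
export) into shared subsystems. A subsystem is retained iff it carries at
least ``min_genes`` measured genes OR at least ``min_metabolites``
annotated metabolites (inclusive disjunction). The output includes the
edge rows (gene -> subsystem, subsystem -> metabolite) behind a Sankey
view; every edge is witnessed by a reaction row.

Currency metabolites (water, protons, ATP, ...) connect essentially every
subsystem and are excluded from metabolite counts by default via a
configurable stop-list.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import DataError

__all__ = ["SubsystemLinkTable", "map_to_subsystems", "DEFAULT_CURRENCY_METABOLITES"]

DEFAULT_CURRENCY_METABOLITES = frozenset(
    {"H2O", "H+", "ATP", "ADP", "AMP", "Pi", "PPi", "NAD+", "NADH", "NADP+", "NADPH", "CO2", "O2", "CoA"}
)


@dataclass
class SubsystemLinkTable:
    summary: pd.DataFrame   # per retained subsystem: gene/metabolite lists and counts
    edges: pd.DataFrame     # source, target, kind in {gene->subsystem, subsystem->metabolite}


def map_to_subsystems(
    profile_genes,
    annotated_metabolites,
    reactions: pd.DataFrame,
    min_genes: int = 2,
    min_metabolites: int = 3,
    currency_metabolites=DEFAULT_CURRENCY_METABOLITES,
    require_same_reaction: bool = False,
) -> SubsystemLinkTable:
    """Collect measured genes and metabolites per subsystem and apply the
    inclusion rule (>= min_genes genes OR >= min_metabolites metabolites).

    ``require_same_reaction=True`` additionally restricts metabolites to
    those sharing a specific reaction with a measured gene (stricter than
    the default subsystem-level co-membership).
    """
    required = {"reaction_id", "subsystem", "gene_id", "metabolite_id"}
    if reactions.empty:
        raise DataError("empty reaction-annotation table")
    if not required.issubset(reactions.columns):
        raise DataError(f"reaction table must have columns {sorted(required)}")
    genes = set(profile_genes)
    mets = set(annotated_metabolites) - set(currency_metabolites or ())

    gene_rows = reactions[reactions["gene_id"].isin(genes)]
    met_rows = reactions[reactions["metabolite_id"].isin(mets)]
    if require_same_reaction:
        met_rows = met_rows[met_rows["reaction_id"].isin(set(gene_rows["reaction_id"]))]

    summary_records, edge_records = [], []
    for subsystem in sorted(reactions["subsystem"].unique()):
        sub_genes = sorted(set(gene_rows.loc[gene_rows["subsystem"] == subsystem, "gene_id"]))
        sub_mets = sorted(set(met_rows.loc[met_rows["subsystem"] == subsystem, "metabolite_id"]))
        if len(sub_genes) >= min_genes or len(sub_mets) >= min_metabolites:
            summary_records.append(
                {
                    "subsystem": subsystem,
                    "genes": ",".join(sub_genes),
                    "metabolites": ",".join(sub_mets),
                    "n_genes": len(sub_genes),
                    "n_metabolites": len(sub_mets),
                }
            )
            edge_records.extend(
                {"source": g, "target": subsystem, "kind": "gene->subsystem"} for g in sub_genes
            )
            edge_records.extend(
                {"source": subsystem, "target": m, "kind": "subsystem->metabolite"}
                for m in sub_mets
            )
    return SubsystemLinkTable(
        summary=pd.DataFrame(
            summary_records,
            columns=["subsystem", "genes", "metabolites", "n_genes", "n_metabolites"],
        ),
        edges=pd.DataFrame(edge_records, columns=["source", "target", "kind"]),
    )
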