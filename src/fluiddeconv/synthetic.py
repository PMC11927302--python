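"""Synthetic multi-omic cohorts with known ground truth.

Everything the pipeline consumes can be generated here: a labeled
single-cell-style reference atlas, bulk body-fluid cohorts mixed from it
with Dirichlet cell-type fractions and multinomial counts at variable
library depth (emulating urine solute/volume variability), planted
differentially expressed genes and enriched pathways, an untargeted
metabolomics feature table with a spectral library containing planted true
matches and near-miss decoys, a gene/metabolite reaction-subsystem table,
and per-sample RNA QC metrics. All randomness flows from a single integer
seed through one numpy Generator, so every fixture is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ReferenceAtlas",
    "SimulationTruth",
    "FeatureTable",
    "SpectralLibrary",
    "make_reference",
    "simulate_bulk_cohort",
    "make_gene_sets",
    "make_metabolite_pathways",
    "make_reaction_table",
    "simulate_metabolome",
    "emit_qc_metrics",
]


@dataclass
class ReferenceAtlas:
    """Cell x gene counts with one cell-type label per cell.

    Stands in for a multidonor whole-body cell atlas. ``marker_genes``
    records which genes were planted as type-specific markers (ground
    truth for profile-derivation tests).
    """

    counts: np.ndarray
    cell_types: np.ndarray
    gene_ids: list
    marker_genes: dict = field(default_factory=dict)

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        self.cell_types = np.asarray(self.cell_types)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a cells x genes matrix")
        if self.counts.shape[0] != self.cell_types.size:
            raise ValueError("one cell-type label required per cell")
        if self.counts.shape[1] != len(self.gene_ids):
            raise ValueError("one gene id required per gene column")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene ids must be unique")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        labels, n = np.unique(self.cell_types, return_counts=True)
        if labels.size < 1 or np.any(n < 2):
            raise ValueError("every cell type needs at least 2 cells")

    @property
    def labels(self) -> np.ndarray:
        return np.unique(self.cell_types)


@dataclass
class SimulationTruth:
    """Ground truth of a simulated cohort, for parameter-recovery tests."""

    true_fractions: pd.DataFrame          # sample x cell type, rows on the simplex
    group_assignment: pd.Series           # sample -> {A, B}
    covariates: pd.DataFrame              # creatinine_mg_dl, volume_ml per sample
    de_genes: dict                        # gene -> planted log2 fold change (B vs A)
    enriched_pathways: list               # pathway ids planted in both omics
    annotation_truth: dict                # feature id -> compound id or None
    seed: int


@dataclass
class FeatureTable:
    """Untargeted LC-MS feature table plus optional MS2 spectra keyed by feature id."""

    table: pd.DataFrame                   # feature_id, mode, mz, rt, per-sample intensities
    spectra: dict


@dataclass
class SpectralLibrary:
    """Reference library: compound table plus optional reference MS2 spectra."""

    table: pd.DataFrame                   # compound_id, mode, mz, rt, inchikey, chemical_class
    spectra: dict


# ------------------------------------------------------------------ atlas

def make_reference(
    n_cell_types: int = 5,
    n_genes: int = 300,
    cells_per_type: int = 30,
    marker_genes_per_type: int = 10,
    expression_dispersion: float = 0.3,
    marker_fold: float = 10.0,
    marker_headroom: float = 2.0,
    seed: int = 0,
) -> ReferenceAtlas:
    """Generate a labeled reference atlas with planted marker genes.

    Each cell type receives ``marker_genes_per_type`` genes whose designed
    mean expression exceeds every other type's mean by at least
    ``marker_fold`` (construction places them at ``marker_fold *
    marker_headroom`` over the best competitor so the guarantee survives
    sampling noise). Counts are negative-binomial around the type means
    with dispersion ``expression_dispersion`` (var = mu + phi * mu^2).
    """
    if n_cell_types < 2:
        raise ValueError("need at least 2 cell types")
    if min(n_genes, cells_per_type, marker_genes_per_type) <= 0:
        raise ValueError("dimensions must be positive")
    if marker_genes_per_type * n_cell_types > n_genes:
        raise ValueError("more marker genes requested than genes available")
    if expression_dispersion <= 0 or marker_fold <= 1:
        raise ValueError("dispersion must be > 0 and marker_fold > 1")

    rng = np.random.default_rng(seed)
    means = rng.lognormal(mean=1.0, sigma=1.0, size=(n_cell_types, n_genes))

    marker_idx = rng.choice(
        n_genes, size=n_cell_types * marker_genes_per_type, replace=False
    ).reshape(n_cell_types, marker_genes_per_type)
    gene_ids = [f"gene_{i:04d}" for i in range(n_genes)]
    labels = [f"CT{c + 1:02d}" for c in range(n_cell_types)]

    marker_map: dict[str, list[str]] = {}
    for c in range(n_cell_types):
        idx = marker_idx[c]
        others = [t for t in range(n_cell_types) if t != c]
        # damp competitors to a low baseline, then place the marker well clear
        means[np.ix_(others, idx)] = rng.uniform(0.1, 1.0, size=(len(others), idx.size))
        means[c, idx] = marker_fold * marker_headroom * np.max(means[others, :][:, idx], axis=0)
        marker_map[labels[c]] = [gene_ids[i] for i in idx]

    phi = expression_dispersion
    cell_type_of_cell = np.repeat(np.arange(n_cell_types), cells_per_type)
    mu = means[cell_type_of_cell]                      # cells x genes
    n_param = 1.0 / phi
    p_param = n_param / (n_param + mu)
    counts = rng.negative_binomial(n_param, p_param)

    return ReferenceAtlas(
        counts=counts,
        cell_types=np.array([labels[c] for c in cell_type_of_cell]),
        gene_ids=gene_ids,
        marker_genes=marker_map,
    )


# ------------------------------------------------------------------ bulk cohort

def _basis_proportions(atlas: ReferenceAtlas) -> pd.DataFrame:
    """Per-type pseudobulk expression as column-stochastic gene proportions."""
    labels = atlas.labels
    cols = {}
    for lab in labels:
        tot = atlas.counts[atlas.cell_types == lab].sum(axis=0).astype(float)
        cols[lab] = tot / tot.sum()
    return pd.DataFrame(cols, index=atlas.gene_ids)


def simulate_bulk_cohort(
    atlas: ReferenceAtlas,
    n_samples_per_group: tuple[int, int] = (6, 12),
    fraction_shift_spec: dict | None = None,
    depth_range: tuple[float, float] = (5e5, 2e6),
    concentration: float | None = 30.0,
    base_fractions: dict | None = None,
    de_spec: dict | None = None,
    covariate_spec: dict | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Mix a two-group bulk cohort from the atlas with known fractions.

    Per sample, cell-type fractions are Dirichlet with concentration vector
    ``concentration * base_fractions``; group B adds ``fraction_shift_spec``
    (cell type -> added concentration) to that vector, which keeps fractions
    on the simplex by construction. ``concentration=None`` gives point-mass
    fractions (the normalized weight vector, no Dirichlet noise). Expected
    gene proportions are the basis-weighted mixture; ``de_spec`` multiplies
    selected genes' expected proportion by 2**lfc in group B (then
    renormalizes). Counts are a single multinomial draw at a depth sampled
    uniformly from ``depth_range``, so each column total equals its drawn
    depth exactly — the depth spread emulates solute/volume variability.
    """
    if depth_range[0] <= 0 or depth_range[1] < depth_range[0]:
        raise ValueError("depth_range must be positive and ordered")
    labels = list(atlas.labels)
    k = len(labels)
    shift = dict(fraction_shift_spec or {})
    unknown = set(shift) - set(labels)
    if unknown:
        raise ValueError(f"shift spec names unknown cell types: {sorted(unknown)}")
    de_spec = dict(de_spec or {})
    unknown_genes = set(de_spec) - set(atlas.gene_ids)
    if unknown_genes:
        raise ValueError(f"de_spec names unknown genes: {sorted(unknown_genes)}")

    rng = np.random.default_rng(seed)
    basis = _basis_proportions(atlas)

    if base_fractions is None:
        base = np.full(k, 1.0 / k)
    else:
        base = np.array([base_fractions[lab] for lab in labels], dtype=float)
        base = base / base.sum()
    shift_vec = np.array([shift.get(lab, 0.0) for lab in labels], dtype=float)

    n_a, n_b = n_samples_per_group
    sample_ids = [f"A{i + 1:02d}" for i in range(n_a)] + [f"B{i + 1:02d}" for i in range(n_b)]
    groups = ["A"] * n_a + ["B"] * n_b

    fracs = np.empty((n_a + n_b, k))
    for i, grp in enumerate(groups):
        if concentration is None:
            w = base + (shift_vec if grp == "B" else 0.0)
            f = w / w.sum()
        else:
            alpha = concentration * base + (shift_vec if grp == "B" else 0.0)
            f = rng.dirichlet(alpha)
        fracs[i] = f / f.sum()

    cov_spec = dict(covariate_spec or {})
    creat = rng.lognormal(np.log(cov_spec.get("creatinine_mean_mg_dl", 100.0)),
                          cov_spec.get("creatinine_sigma", 0.4), size=n_a + n_b)
    vol = rng.uniform(*cov_spec.get("volume_range_ml", (2.0, 8.0)), size=n_a + n_b)

    bmat = basis.to_numpy()                            # genes x types
    lfc_mult = np.ones(len(atlas.gene_ids))
    gene_pos = {g: i for i, g in enumerate(atlas.gene_ids)}
    for g, lfc in de_spec.items():
        lfc_mult[gene_pos[g]] = 2.0 ** lfc

    counts = np.empty((len(atlas.gene_ids), n_a + n_b), dtype=np.int64)
    lo, hi = int(depth_range[0]), int(depth_range[1])
    for i, grp in enumerate(groups):
        p = bmat @ fracs[i]
        if grp == "B":
            p = p * lfc_mult
        p = p / p.sum()
        depth = int(rng.integers(lo, hi + 1))
        counts[:, i] = rng.multinomial(depth, p)

    counts_df = pd.DataFrame(counts, index=atlas.gene_ids, columns=sample_ids)
    truth = SimulationTruth(
        true_fractions=pd.DataFrame(fracs, index=sample_ids, columns=labels),
        group_assignment=pd.Series(groups, index=sample_ids, name="group"),
        covariates=pd.DataFrame(
            {"creatinine_mg_dl": creat, "volume_ml": vol}, index=sample_ids
        ),
        de_genes=de_spec,
        enriched_pathways=[],
        annotation_truth={},
        seed=seed,
    )
    return counts_df, truth


# ------------------------------------------------------------------ pathways / reactions

def make_gene_sets(
    gene_ids,
    planted_genes,
    n_sets: int = 20,
    set_size: int = 15,
    planted_name: str = "pathway_00_planted",
    seed: int = 0,
) -> dict:
    """Random gene-set collection with one planted set equal to the given genes."""
    rng = np.random.default_rng(seed)
    gene_ids = list(gene_ids)
    sets = {planted_name: set(planted_genes)}
    for i in range(1, n_sets):
        sets[f"pathway_{i:02d}"] = set(rng.choice(gene_ids, size=set_size, replace=False))
    return sets


def make_metabolite_pathways(
    pathway_names, metabolites_per_pathway: int = 8, seed: int = 0
) -> dict:
    """Pathway -> metabolite-id lists sharing the gene-set pathway namespace."""
    rng = np.random.default_rng(seed)
    out = {}
    counter = 0
    for name in pathway_names:
        mets = [f"met_{counter + j:03d}" for j in range(metabolites_per_pathway)]
        counter += metabolites_per_pathway
        rng.shuffle(mets)
        out[name] = mets
    return out


def make_reaction_table(subsystem_spec: dict, seed: int = 0) -> pd.DataFrame:
    """Reaction-annotation rows (reaction_id, subsystem, gene_id, metabolite_id).

    ``subsystem_spec`` maps subsystem label -> (gene ids, metabolite ids).
    Each participant gets its own row under a shared per-subsystem reaction,
    emulating a genome-scale metabolic model export.
    """
    rows = []
    for s_idx, (subsystem, (genes, mets)) in enumerate(sorted(subsystem_spec.items())):
        rid = f"R{s_idx:03d}"
        for g in genes:
            rows.append((rid, subsystem, g, None))
        for m in mets:
            rows.append((rid, subsystem, None, m))
    return pd.DataFrame(rows, columns=["reaction_id", "subsystem", "gene_id", "metabolite_id"])


# ------------------------------------------------------------------ metabolome

def _random_spectrum(rng, precursor_mz, n_peaks=6):
    mz = np.sort(rng.uniform(50.0, max(precursor_mz - 1.0, 60.0), size=n_peaks))
    inten = rng.uniform(0.05, 1.0, size=n_peaks)
    return np.column_stack([mz, inten])


def simulate_metabolome(
    pathway_table: dict,
    enriched_pathway_ids,
    n_features: int = 120,
    n_decoys: int = 15,
    tolerance_margins: dict | None = None,
    ms1_tol: float = 0.01,
    ms2_tol: float = 0.015,
    rt_tol: float = 0.4,
    mz_noise: float = 0.003,
    rt_noise: float = 0.05,
    n_samples: int = 18,
    seed: int = 0,
) -> tuple[FeatureTable, SpectralLibrary, dict]:
    """Feature table + spectral library with planted matches and decoys.

    Every metabolite of the pathways in ``enriched_pathway_ids`` (plus random
    extras up to the match budget) gets a feature placed within all
    tolerances of its library entry, with an MS2 spectrum that is a noisy
    copy of the reference. Decoys copy a library entry but are offset in
    exactly ONE dimension (precursor mass, retention time, or every MS2
    fragment) by tolerance + margin, so each tolerance rule is isolated.
    Remaining features are fillers far from any library mass. Returns the
    feature table, the library, and feature -> compound-or-None truth.
    """
    margins = {"ms1": 0.002, "rt": 0.1, "ms2": 0.005}
    margins.update(tolerance_margins or {})
    all_mets = sorted({m for mets in pathway_table.values() for m in mets})
    if not all_mets:
        raise ValueError("pathway table yields an empty library")
    rng = np.random.default_rng(seed)

    # library masses keep a minimum spacing of 3x (tolerance + margin) so a
    # decoy offset from one entry can never fall inside another entry's window
    spacing = 3.0 * (ms1_tol + margins["ms1"])
    accepted: list[float] = []
    while len(accepted) < len(all_mets):
        cand = float(rng.uniform(100.0, 800.0))
        if all(abs(cand - m) >= spacing for m in accepted):
            accepted.append(cand)

    lib_rows, lib_spectra = [], {}
    for i, met in enumerate(all_mets):
        mode = "pos" if rng.random() < 0.5 else "neg"
        mz = accepted[i]
        rt = float(rng.uniform(1.0, 12.0))
        lib_rows.append(
            {
                "compound_id": met,
                "mode": mode,
                "mz": mz,
                "rt": rt,
                "inchikey": f"SYNTHKEY{i:05d}",
                "chemical_class": f"class_{i % 6}",
            }
        )
        lib_spectra[met] = _random_spectrum(rng, mz)
    library = pd.DataFrame(lib_rows)
    lib_by_id = library.set_index("compound_id")

    planted = sorted({m for p in enriched_pathway_ids for m in pathway_table[p]})
    extra_budget = max(0, min(len(all_mets), n_features // 3) - len(planted))
    pool = [m for m in all_mets if m not in planted]
    extras = list(rng.choice(pool, size=min(extra_budget, len(pool)), replace=False)) if pool else []
    true_matches = planted + extras
    if n_features < len(true_matches) + n_decoys:
        raise ValueError("n_features too small for the planted matches and decoys")

    feat_rows, feat_spectra, truth = [], {}, {}
    sample_cols = [f"S{j + 1:02d}" for j in range(n_samples)]

    def add_feature(fid, mode, mz, rt, spectrum, compound):
        inten = rng.lognormal(10.0, 1.0, size=n_samples)
        row = {"feature_id": fid, "mode": mode, "mz": mz, "rt": rt}
        row.update(dict(zip(sample_cols, inten)))
        feat_rows.append(row)
        if spectrum is not None:
            feat_spectra[fid] = spectrum
        truth[fid] = compound

    fid_counter = 0
    for met in true_matches:
        entry = lib_by_id.loc[met]
        ref = lib_spectra[met]
        noisy = ref.copy()
        noisy[:, 0] += rng.uniform(-mz_noise, mz_noise, size=ref.shape[0])
        noisy[:, 1] *= rng.uniform(0.8, 1.2, size=ref.shape[0])
        add_feature(
            f"F{fid_counter:04d}",
            entry["mode"],
            float(entry["mz"] + rng.uniform(-mz_noise, mz_noise)),
            float(entry["rt"] + rng.uniform(-rt_noise, rt_noise)),
            noisy,
            met,
        )
        fid_counter += 1

    decoy_kinds = ["ms1", "rt", "ms2"]
    decoy_sources = rng.choice(all_mets, size=n_decoys, replace=n_decoys > len(all_mets))
    for j, met in enumerate(decoy_sources):
        entry = lib_by_id.loc[met]
        kind = decoy_kinds[j % 3]
        mz, rt = float(entry["mz"]), float(entry["rt"])
        spec = lib_spectra[met].copy()
        sign = 1 if rng.random() < 0.5 else -1
        if kind == "ms1":
            mz += sign * (ms1_tol + margins["ms1"])
        elif kind == "rt":
            rt += sign * (rt_tol + margins["rt"])
        else:  # shift every fragment beyond the MS2 tolerance
            spec[:, 0] += ms2_tol + margins["ms2"]
        add_feature(f"F{fid_counter:04d}", entry["mode"], mz, rt, spec, None)
        fid_counter += 1

    lib_mz = library["mz"].to_numpy()
    while fid_counter < n_features:
        mz = float(rng.uniform(60.0, 900.0))
        if np.min(np.abs(lib_mz - mz)) <= ms1_tol + margins["ms1"]:
            continue
        add_feature(
            f"F{fid_counter:04d}",
            "pos" if rng.random() < 0.5 else "neg",
            mz,
            float(rng.uniform(1.0, 12.0)),
            None,
            None,
        )
        fid_counter += 1

    features = FeatureTable(table=pd.DataFrame(feat_rows), spectra=feat_spectra)
    return features, SpectralLibrary(table=library, spectra=lib_spectra), truth


# ------------------------------------------------------------------ QC metrics

def emit_qc_metrics(n_samples: int, failing_spec: dict | None = None, seed: int = 0) -> pd.DataFrame:
    """Per-sample RNA QC metrics (3' bias, intron/exon ratio, ribosomal fraction).

    Baseline values sit comfortably inside typical passing ranges;
    ``failing_spec`` maps sample id -> {metric: value} overrides used to
    plant violations.
    """
    rng = np.random.default_rng(seed)
    ids = [f"S{i + 1:02d}" for i in range(n_samples)]
    df = pd.DataFrame(
        {
            "three_prime_bias": rng.uniform(0.2, 0.4, size=n_samples),
            "intron_exon_ratio": rng.uniform(0.2, 0.4, size=n_samples),
            "ribosomal_fraction": rng.uniform(0.1, 0.3, size=n_samples),
        },
        index=pd.Index(ids, name="sample_id"),
    )
    for sid, overrides in (failing_spec or {}).items():
        for metric, value in overrides.items():
            df.loc[sid, metric] = value
    return df
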