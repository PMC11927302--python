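"""End-to-end orchestration of the body-fluid multi-omic workflow.

``run_pipeline`` executes an ordered subset of steps (simulate -> qc ->
normalize -> basis -> deconvolve -> score -> de -> annotate -> enrich ->
integrate) from a single validated config. Steps exchange plain files on
disk in the configured output directory, so any step can be rerun in
isolation; a JSON manifest echoes the effective configuration, the files
each step produced, and headline metrics. One global seed fans out to
per-step seeds through fixed offsets, keeping deterministic steps
byte-reproducible under reruns.
"""

from __future__ import annotations

import json
import hashlib
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as fio
from .basis import CellTypeProfile, basis_collinearity, derive_profiles, pseudobulk
from .de import bootstrap_logfc_ci, fit_de
from .deconvolution import FractionTable, compare_groups, deconvolve, zero_small_fractions
from .enrichment import enrich_sets, joint_pathways
from .errors import ConfigError, DependencyError
from .integration import map_to_subsystems
from .metabolome import annotate_features
from .normalization import log_norm, tmm_factors
from .qc import DEFAULT_THRESHOLDS, apply_qc
from .scoring import filter_counts, score_table
from .synthetic import (
    FeatureTable,
    SpectralLibrary,
    emit_qc_metrics,
    make_gene_sets,
    make_metabolite_pathways,
    make_reaction_table,
    make_reference,
    simulate_bulk_cohort,
    simulate_metabolome,
)

__all__ = ["RunConfig", "run_pipeline", "STEP_ORDER", "STEP_DEPS"]

STEP_ORDER = [
    "simulate",
    "qc",
    "normalize",
    "basis",
    "deconvolve",
    "score",
    "de",
    "annotate",
    "enrich",
    "integrate",
]

STEP_DEPS = {
    "simulate": [],
    "qc": ["simulate"],
    "normalize": ["simulate"],
    "basis": ["simulate"],
    "deconvolve": ["simulate", "basis"],
    "score": ["normalize", "basis"],
    "de": ["simulate"],
    "annotate": ["simulate"],
    "enrich": ["de", "annotate", "simulate"],
    "integrate": ["basis", "annotate", "simulate"],
}

# files whose presence marks a step's outputs as available on disk
_STEP_SENTINELS = {
    "simulate": "bulk_counts.tsv",
    "qc": "qc_result.csv",
    "normalize": "normalized.tsv",
    "basis": "basis.tsv",
    "deconvolve": "fractions.tsv",
    "score": "signature_scores.tsv",
    "de": "de_results.tsv",
    "annotate": "annotations.tsv",
    "enrich": "joint_pathways.tsv",
    "integrate": "subsystem_edges.tsv",
}

_SEED_OFFSETS = {"simulate": 0, "deconvolve": 101, "de": 202, "annotate": 303}

_KNOWN_KEYS = {"outdir", "seed"} | set(STEP_ORDER)


class RunConfig:
    """Validated pipeline configuration.

    Top-level keys: ``outdir``, ``seed``, and one optional parameter dict
    per step. Unknown keys are rejected.
    """

    def __init__(self, config: dict):
        unknown = set(config) - _KNOWN_KEYS
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "outdir" not in config:
            raise ConfigError("config requires 'outdir'")
        self.outdir = Path(config["outdir"])
        self.seed = int(config.get("seed", 0))
        self.params = {step: dict(config.get(step) or {}) for step in STEP_ORDER}
        self._raw = {"outdir": str(self.outdir), "seed": self.seed}
        self._raw.update({s: self.params[s] for s in STEP_ORDER if self.params[s]})

    def step_seed(self, step: str) -> int:
        return (self.seed + _SEED_OFFSETS.get(step, 0)) % (2**31)

    def as_dict(self) -> dict:
        return json.loads(json.dumps(self._raw))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls(yaml.safe_load(fh))


def _profiles_from_gmt(path) -> list[CellTypeProfile]:
    return [
        CellTypeProfile(name, frozenset(genes), {"source": "gmt"})
        for name, genes in fio.read_gmt(path).items()
    ]


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


# ------------------------------------------------------------------ steps

def _step_simulate(cfg: RunConfig, out: Path) -> tuple[list, dict]:
    p = cfg.params["simulate"]
    seed = cfg.step_seed("simulate")
    atlas = make_reference(
        n_cell_types=p.get("n_cell_types", 5),
        n_genes=p.get("n_genes", 400),
        cells_per_type=p.get("cells_per_type", 30),
        marker_genes_per_type=p.get("marker_genes_per_type", 12),
        seed=seed,
    )
    shift_ct = p.get("shift_cell_type", atlas.labels[0])
    shift = {shift_ct: p.get("shift_concentration", 15.0)}
    n_de = p.get("n_de_genes", 25)
    lfc = p.get("de_log2fc", 2.0)
    # plant DE in non-marker genes so the fraction shift and the expression
    # effect stay separable
    marker_set = {g for genes in atlas.marker_genes.values() for g in genes}
    rng = np.random.default_rng(seed + 1)
    candidates = [g for g in atlas.gene_ids if g not in marker_set]
    de_genes = {g: lfc for g in rng.choice(candidates, size=n_de, replace=False)}

    counts, truth = simulate_bulk_cohort(
        atlas,
        n_samples_per_group=tuple(p.get("n_samples_per_group", (6, 12))),
        fraction_shift_spec=shift,
        depth_range=tuple(p.get("depth_range", (1e5, 4e5))),
        concentration=p.get("concentration", 30.0),
        de_spec=de_genes,
        seed=seed + 2,
    )

    planted_pathway = "pathway_00_planted"
    gene_sets = make_gene_sets(
        atlas.gene_ids, sorted(de_genes), n_sets=p.get("n_pathways", 15), seed=seed + 3,
        planted_name=planted_pathway,
    )
    met_pathways = make_metabolite_pathways(sorted(gene_sets), seed=seed + 4)
    features, library, ann_truth = simulate_metabolome(
        met_pathways,
        [planted_pathway],
        n_features=p.get("n_features", 120),
        n_decoys=p.get("n_decoys", 12),
        seed=seed + 5,
    )
    subsystem_spec = {
        f"subsystem_{i:02d}": (sorted(genes)[:4], met_pathways[name][:5])
        for i, (name, genes) in enumerate(sorted(gene_sets.items()))
    }
    reactions = make_reaction_table(subsystem_spec)
    qc_metrics = emit_qc_metrics(counts.shape[1], seed=seed + 6)
    qc_metrics.index = counts.columns

    truth.enriched_pathways = [planted_pathway]
    truth.annotation_truth = ann_truth

    # persist everything downstream steps read
    fio.write_counts_tsv(counts, out / "bulk_counts.tsv")
    fio.write_counts_mtx(counts, out / "bulk_counts")
    atlas_df = pd.DataFrame(atlas.counts.T, index=atlas.gene_ids,
                            columns=[f"cell_{i}" for i in range(atlas.counts.shape[0])])
    fio.write_counts_mtx(atlas_df, out / "atlas")
    pd.Series(atlas.cell_types, name="cell_type").to_csv(out / "atlas.cell_types.tsv", sep="\t", index=False)
    truth.group_assignment.to_csv(out / "groups.csv")
    truth.covariates.to_csv(out / "covariates.csv", index_label="sample_id")
    qc_metrics.to_csv(out / "qc_metrics.csv")
    fio.write_gmt(gene_sets, out / "gene_sets.gmt")
    fio.write_gmt(met_pathways, out / "met_sets.gmt")
    features.table.to_csv(out / "features.csv", index=False)
    fio.write_mgf(features.spectra, out / "features.mgf")
    library.table.to_csv(out / "library.csv", index=False)
    fio.write_mgf(library.spectra, out / "library.mgf")
    reactions.to_csv(out / "reactions.csv", index=False)
    with open(out / "truth.json", "w") as fh:
        json.dump(
            {
                "true_fractions": truth.true_fractions.to_dict(),
                "groups": truth.group_assignment.to_dict(),
                "de_genes": truth.de_genes,
                "enriched_pathways": truth.enriched_pathways,
                "annotation_truth": truth.annotation_truth,
                "seed": truth.seed,
            },
            fh,
            indent=1,
        )
    files = [
        "bulk_counts.tsv", "bulk_counts.mtx", "atlas.mtx", "atlas.cell_types.tsv",
        "groups.csv", "covariates.csv", "qc_metrics.csv", "gene_sets.gmt",
        "met_sets.gmt", "features.csv", "features.mgf", "library.csv",
        "library.mgf", "reactions.csv", "truth.json",
    ]
    return files, {"n_samples": counts.shape[1], "n_genes": counts.shape[0]}


def _step_qc(cfg: RunConfig, out: Path) -> tuple[list, dict]:
    p = cfg.params["qc"]
    metrics = pd.read_csv(out / "qc_metrics.csv", index_col=0)
    thresholds = {
        k: tuple(v) for k, v in p.get("thresholds", dict(DEFAULT_THRESHOLDS)).items()
    }
    result = apply_qc(metrics, thresholds)
    result.to_csv(out / "qc_result.csv")
    return ["qc_result.csv"], {"n_pass": int(result["qc_pass"].sum())}


def _step_normalize(cfg: RunConfig, out: Path) -> tuple[list, dict]:
    p = cfg.params["normalize"]
    counts = fio.read_counts_tsv(out / "bulk_counts.tsv")
    factors = tmm_factors(counts)
    norm = log_norm(counts, factors, pseudocount=p.get("pseudocount", 1.0))
    factors.to_csv(out / "tmm_factors.tsv", sep="\t")
    norm.to_csv(out / "normalized.tsv", sep="\t", index_label="gene_id")
    return ["tmm_factors.tsv", "normalized.tsv"], {}


def _step_basis(cfg: RunConfig, out: Path) -> tuple[list, dict]:
    from .synthetic import ReferenceAtlas

    p = cfg.params["basis"]
    atlas_df = fio.read_counts_mtx(out / "atlas")
    labels = pd.read_csv(out / "atlas.cell_types.tsv", sep="\t")["cell_type"].to_numpy()
    atlas = ReferenceAtlas(atlas_df.to_numpy().T, labels, atlas_df.index.tolist())
    bmat = pseudobulk(atlas)
    profiles = derive_profiles(
        bmat, fold_threshold=p.get("fold_threshold", 10.0), min_cpm=p.get("min_cpm", 10.0)
    )
    coll = basis_collinearity(bmat)
    bmat.to_csv(out / "basis.tsv", sep="\t", index_label="gene_id")
    fio.write_gmt({pr.cell_type: pr.genes for pr in profiles}, out / "profiles.gmt")
    coll.to_csv(out / "basis_collinearity.tsv", sep="\t")
    return ["basis.tsv", "profiles.gmt", "basis_collinearity.tsv"], {
        "n_profiles": len(profiles)
    }


def _step_deconvolve(cfg: RunConfig, out: Path) -> tuple[list, dict]:
    p = cfg.params["deconvolve"]
    counts = fio.read_counts_tsv(out / "bulk_counts.tsv")
    bmat = pd.read_csv(out / "basis.tsv", sep="\t", index_col=0)
    profiles = fio.read_gmt(out / "profiles.gmt")
    gene_universe = sorted(set().union(*profiles.values())) if profiles else list(bmat.index)
    if p.get("restrict_to_profile_genes", True):
        bmat = bmat.loc[[g for g in gene_universe if g in bmat.index]]
    ft = deconvolve(counts, bmat, method=p.get("method", "nnls"))
    ft = zero_small_fractions(ft, threshold=p.get("zero_threshold", 0.001))
    groups = pd.read_csv(out / "groups.csv", index_col=0)["group"]
    grp_a = ft.fractions.index[groups.reindex(ft.fractions.index) == "A"]
    grp_b = ft.fractions.index[groups.reindex(ft.fractions.index) == "B"]
    comparison = compare_groups(
        FractionTable(ft.fractions.loc[grp_a], ft.residual.loc[grp_a]),
        FractionTable(ft.fractions.loc[grp_b], ft.residual.loc[grp_b]),
    )
    ft.fractions.to_csv(out / "fractions.tsv", sep="\t", index_label="sample_id")
    ft.residual.to_csv(out / "residuals.tsv", sep="\t")
    comparison.to_csv(out / "fraction_comparison.tsv", sep="\t")
    return ["fractions.tsv", "residuals.tsv", "fraction_comparison.tsv"], {
        "n_significant_cell_types": int(comparison["significant"].sum())
    }


def _step_score(cfg: RunConfig, out: Path) -> tuple[list, dict]:
    norm = pd.read_csv(out / "normalized.tsv", sep="\t", index_col=0)
    profiles = _profiles_from_gmt(out / "profiles.gmt")
    table = score_table(norm, profiles)
    table.scores.to_csv(out / "signature_scores.tsv", sep="\t", index_label="sample_id")
    table.n_genes_used.to_csv(out / "signature_n_genes.tsv", sep="\t")
    return ["signature_scores.tsv", "signature_n_genes.tsv"], {}


def _step_de(cfg: RunConfig, out: Path) -> tuple[list, dict]:
    p = cfg.params["de"]
    counts = fio.read_counts_tsv(out / "bulk_counts.tsv")
    groups = pd.read_csv(out / "groups.csv", index_col=0)["group"]
    covariates = pd.read_csv(out / "covariates.csv", index_col=0)
    result = fit_de(counts, groups, covariates=covariates)
    files = ["de_results.tsv"]
    if p.get("bootstrap_ci", False):
        top = result.index[result["significant"]][: p.get("n_ci_genes", 10)]
        if len(top):
            ci = bootstrap_logfc_ci(
                counts, groups, top, covariates=covariates,
                n_boot=p.get("n_boot", 200), seed=cfg.step_seed("de"),
            )
            ci.to_csv(out / "de_logfc_ci.tsv", sep="\t")
            files.append("de_logfc_ci.tsv")
    result.to_csv(out / "de_results.tsv", sep="\t", index_label="gene_id")
    return files, {"n_significant_genes": int(result["significant"].sum())}


def _step_annotate(cfg: RunConfig, out: Path) -> tuple[list, dict]:
    p = cfg.params["annotate"]
    features = FeatureTable(
        table=pd.read_csv(out / "features.csv"), spectra=fio.read_mgf(out / "features.mgf")
    )
    library = SpectralLibrary(
        table=pd.read_csv(out / "library.csv"), spectra=fio.read_mgf(out / "library.mgf")
    )
    ann = annotate_features(
        features,
        library,
        ms1_tol=p.get("ms1_tol", 0.01),
        ms2_tol=p.get("ms2_tol", 0.015),
        rt_tol=p.get("rt_tol", 0.4),
        min_ms2_similarity=p.get("min_ms2_similarity", 0.7),
    )
    ann.to_csv(out / "annotations.tsv", sep="\t")
    return ["annotations.tsv"], {"n_annotated": int(ann["compound_id"].notna().sum())}


def _step_enrich(cfg: RunConfig, out: Path) -> tuple[list, dict]:
    p = cfg.params["enrich"]
    alpha = p.get("alpha", 0.05)
    de_res = pd.read_csv(out / "de_results.tsv", sep="\t", index_col=0)
    gene_sets = fio.read_gmt(out / "gene_sets.gmt")
    rna_query = de_res.index[de_res["significant"]].tolist()
    rna = enrich_sets(rna_query, gene_sets, universe=de_res.index, alpha=alpha)

    ann = pd.read_csv(out / "annotations.tsv", sep="\t", index_col=0)
    met_sets = fio.read_gmt(out / "met_sets.gmt")
    library = pd.read_csv(out / "library.csv")
    met_query = ann["compound_id"].dropna().unique().tolist()
    met = enrich_sets(met_query, met_sets, universe=library["compound_id"], alpha=alpha)

    joint = joint_pathways(rna, met, alpha=alpha)
    rna.to_csv(out / "enrichment_rna.tsv", sep="\t")
    met.to_csv(out / "enrichment_met.tsv", sep="\t")
    joint.to_csv(out / "joint_pathways.tsv", sep="\t")
    return ["enrichment_rna.tsv", "enrichment_met.tsv", "joint_pathways.tsv"], {
        "n_joint_pathways": len(joint)
    }


def _step_integrate(cfg: RunConfig, out: Path) -> tuple[list, dict]:
    p = cfg.params["integrate"]
    profiles = fio.read_gmt(out / "profiles.gmt")
    profile_genes = set().union(*profiles.values()) if profiles else set()
    ann = pd.read_csv(out / "annotations.tsv", sep="\t", index_col=0)
    reactions = pd.read_csv(out / "reactions.csv")
    table = map_to_subsystems(
        profile_genes,
        ann["compound_id"].dropna().unique(),
        reactions,
        min_genes=p.get("min_genes", 2),
        min_metabolites=p.get("min_metabolites", 3),
    )
    table.summary.to_csv(out / "subsystems.tsv", sep="\t", index=False)
    table.edges.to_csv(out / "subsystem_edges.tsv", sep="\t", index=False)
    return ["subsystems.tsv", "subsystem_edges.tsv"], {
        "n_subsystems": len(table.summary)
    }


_STEP_FUNCS = {
    "simulate": _step_simulate,
    "qc": _step_qc,
    "normalize": _step_normalize,
    "basis": _step_basis,
    "deconvolve": _step_deconvolve,
    "score": _step_score,
    "de": _step_de,
    "annotate": _step_annotate,
    "enrich": _step_enrich,
    "integrate": _step_integrate,
}


def run_pipeline(config: RunConfig | dict, steps=None) -> dict:
    """Run the requested steps in canonical order and write a manifest.

    Every step's dependencies must either appear earlier in ``steps`` or
    already have outputs in the configured directory; otherwise a
    ``DependencyError`` is raised before any computation runs.
    """
    cfg = config if isinstance(config, RunConfig) else RunConfig(config)
    steps = list(STEP_ORDER) if steps is None else list(steps)
    unknown = set(steps) - set(STEP_ORDER)
    if unknown:
        raise ConfigError(f"unknown steps: {sorted(unknown)}")
    steps = [s for s in STEP_ORDER if s in steps]
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)

    # validate the whole plan before running anything
    planned = set()
    for step in steps:
        for dep in STEP_DEPS[step]:
            if dep in planned or (out / _STEP_SENTINELS[dep]).exists():
                continue
            raise DependencyError(f"step {step!r} requires {dep!r} (not planned, no outputs found)")
        planned.add(step)

    manifest = {"config": cfg.as_dict(), "steps": {}}
    for step in steps:
        files, metrics = _STEP_FUNCS[step](cfg, out)
        manifest["steps"][step] = {
            "files": {f: _sha256(out / f) for f in files if (out / f).exists()},
            "metrics": metrics,
            "seed": cfg.step_seed(step),
        }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
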