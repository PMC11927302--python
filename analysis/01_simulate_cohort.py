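"""Generate the synthetic two-group body-fluid cohort with known truth.

Builds a 5-cell-type reference atlas, mixes an 6-vs-12-sample bulk cohort
with a planted fraction shift in one cell type and a planted DE gene
module, and generates the matching metabolomics feature table, spectral
library, reaction table and QC metrics. Everything lands in
results/analysis/run/ for the downstream scripts.
"""

import json
import warnings

from _paths import OUTDIR, SEED
from fluiddeconv.pipeline import run_pipeline

if __name__ == "__main__":
    warnings.filterwarnings("ignore")
    manifest = run_pipeline({"outdir": OUTDIR, "seed": SEED}, steps=["simulate"])
    truth = json.loads((OUTDIR / "truth.json").read_text())
    n_b = sum(1 for g in truth["groups"].values() if g == "B")
    print(f"cohort: {manifest['steps']['simulate']['metrics']} "
          f"({len(truth['groups']) - n_b} group A vs {n_b} group B)")
    print(f"planted DE genes: {len(truth['de_genes'])}; "
          f"planted pathway: {truth['enriched_pathways']}")
    print(f"outputs in {OUTDIR}")
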