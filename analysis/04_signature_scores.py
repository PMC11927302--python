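"""Normalize the cohort and score cell-type signatures per sample.

Applies CPM + TMM + log2 normalization, averages each cell-type profile's
normalized expression per sample, and compares the shifted cell type's
score between groups with a Mann-Whitney test.
"""

import warnings

import pandas as pd

from _paths import OUTDIR, SEED
from fluiddeconv.pipeline import run_pipeline
from fluiddeconv.scoring import compare_signature

if __name__ == "__main__":
    warnings.filterwarnings("ignore")
    run_pipeline({"outdir": OUTDIR, "seed": SEED}, steps=["normalize", "score"])
    scores = pd.read_csv(OUTDIR / "signature_scores.tsv", sep="\t", index_col=0)
    groups = pd.read_csv(OUTDIR / "groups.csv", index_col=0)["group"]
    print("mean signature score per cell type and group (log2 CPM units):")
    print(scores.groupby(groups).mean().round(2).to_string())
    for ct in scores.columns:
        a = scores.loc[groups == "A", ct]
        b = scores.loc[groups == "B", ct]
        u, p = compare_signature(a, b)
        flag = " *" if p < 0.05 else ""
        print(f"{ct}: U={u:.0f}, two-sided p={p:.3g}{flag}")
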