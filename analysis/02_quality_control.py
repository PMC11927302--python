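"""Apply sample-level RNA QC thresholds to the simulated metric table.

Metrics are rounded to the nearest tenth before comparison; the ribosomal
read fraction threshold is 0.5. Writes qc_result.csv.
"""

import warnings

from _paths import OUTDIR, SEED
from fluiddeconv.pipeline import run_pipeline

if __name__ == "__main__":
    warnings.filterwarnings("ignore")
    manifest = run_pipeline({"outdir": OUTDIR, "seed": SEED}, steps=["qc"])
    print(f"QC: {manifest['steps']['qc']['metrics']['n_pass']} samples pass")
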