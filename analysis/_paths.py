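"""Shared output location and seed for the numbered analysis scripts."""

from pathlib import Path

OUTDIR = Path(__file__).resolve().parent.parent / "results" / "analysis" / "run"
SEED = 20240601
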