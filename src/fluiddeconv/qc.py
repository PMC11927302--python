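"""Sample-level RNA QC filtering.

Each metric is rounded to the nearest tenth before comparison against its
threshold (half rounded away from zero, the spreadsheet convention, so
0.54 -> 0.5 passes a <= 0.5 bound and 0.56 -> 0.6 fails it). Bounds are
inclusive after rounding. The ribosomal read fraction threshold defaults
to 0.5; directions and bounds for 3' bias and intron/exon ratio are
deliberately user-supplied — there is no universal convention for them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ConfigError

__all__ = ["apply_qc", "round_to_tenth", "DEFAULT_THRESHOLDS"]

#: metric -> (bound, direction); direction "le" means pass iff rounded value <= bound
DEFAULT_THRESHOLDS = {"ribosomal_fraction": (0.5, "le")}


def round_to_tenth(x, mode: str = "half-away") -> np.ndarray:
    """Round to one decimal, half away from zero by default ("half-even" optional)."""
    x = np.asarray(x, dtype=float)
    if mode == "half-even":
        return np.round(x, 1)
    if mode != "half-away":
        raise ConfigError(f"unknown rounding mode {mode!r}")
    return np.sign(x) * np.floor(np.abs(x) * 10.0 + 0.5) / 10.0


def apply_qc(
    metrics: pd.DataFrame,
    thresholds: dict | None = None,
    rounding: str = "half-away",
) -> pd.DataFrame:
    """Pass/fail each sample against per-metric thresholds.

    ``thresholds`` maps metric name -> (bound, direction) with direction in
    {"le", "ge"}. A sample passes iff every thresholded metric, rounded to
    the nearest tenth, satisfies its (inclusive) bound. Returns the metric
    table augmented with ``qc_pass`` and a comma-joined ``failed_metrics``
    column. Idempotent and monotone: worsening a metric never flips a FAIL
    to a PASS.
    """
    thresholds = dict(DEFAULT_THRESHOLDS if thresholds is None else thresholds)
    missing = set(thresholds) - set(metrics.columns)
    if missing:
        raise ConfigError(f"thresholds given for absent metrics: {sorted(missing)}")

    out = metrics.copy()
    failed_lists = [[] for _ in range(len(metrics))]
    for metric, (bound, direction) in thresholds.items():
        if direction not in ("le", "ge"):
            raise ConfigError(f"direction for {metric!r} must be 'le' or 'ge'")
        rounded = round_to_tenth(metrics[metric].to_numpy(), mode=rounding)
        ok = rounded <= bound if direction == "le" else rounded >= bound
        for i, good in enumerate(ok):
            if not good:
                failed_lists[i].append(metric)
    out["qc_pass"] = [not f for f in failed_lists]
    out["failed_metrics"] = [",".join(f) for f in failed_lists]
    return out
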