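"""Untargeted LC-MS/MS feature annotation against a spectral library.

Annotation evidence cascades through three orthogonal tolerances:
precursor accurate mass (MS1, default 0.01 Da), method-specific retention
time (default +/- 0.4 min, enforced only when the library entry has a
known RT), and MS2 fragment matching (default 0.015 Da) scored as the
cosine of square-root intensities over greedily paired peaks. When both
the feature and the candidate carry MS2 spectra, the similarity gate is
mandatory — a dissimilar spectrum rejects the candidate even if mass and
RT agree. Positive- and negative-mode entries are never cross-matched
(separate injections acquire them independently).

Match levels: ``ms1_rt_ms2`` (mass + RT + passing MS2), ``ms1_rt``
(mass + RT, no MS2 available), ``ms1_only`` (library RT unknown). The
best candidate per feature is chosen by level, then MS2 similarity, then
smallest mass error, with remaining ties broken lexicographically on
compound id, so annotation is deterministic and independent of library
row order.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import DataError
from .synthetic import FeatureTable, SpectralLibrary

__all__ = ["ms2_cosine", "annotate_features", "class_summary"]

_LEVEL_RANK = {"ms1_rt_ms2": 3, "ms1_rt": 2, "ms1_only": 1}


def ms2_cosine(spectrum_a, spectrum_b, ms2_tol: float = 0.015) -> float:
    """Cosine similarity of two peak lists with greedy fragment pairing.

    Peaks are paired closest-mass-first within ``ms2_tol``, each peak used
    at most once; the score is the cosine of the square-root intensity
    vectors (unmatched peaks contribute only to the norms). Symmetric and
    1.0 for identical spectra, 0.0 when no peak pair falls within
    tolerance.
    """
    a = np.asarray(spectrum_a, dtype=float)
    b = np.asarray(spectrum_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("spectra must be non-empty")
    if a.ndim != 2 or b.ndim != 2 or a.shape[1] != 2 or b.shape[1] != 2:
        raise ValueError("spectra must be (n, 2) arrays of (m/z, intensity)")
    if np.any(a[:, 1] < 0) or np.any(b[:, 1] < 0):
        raise DataError("negative peak intensity")

    diff = np.abs(a[:, 0][:, None] - b[:, 0][None, :])
    pairs = np.argwhere(diff <= ms2_tol)
    order = np.argsort(diff[pairs[:, 0], pairs[:, 1]], kind="mergesort")
    used_a = np.zeros(a.shape[0], dtype=bool)
    used_b = np.zeros(b.shape[0], dtype=bool)
    dot = 0.0
    for i, j in pairs[order]:
        if used_a[i] or used_b[j]:
            continue
        used_a[i] = used_b[j] = True
        dot += np.sqrt(a[i, 1] * b[j, 1])
    norm = np.sqrt(a[:, 1].sum()) * np.sqrt(b[:, 1].sum())
    if norm == 0:
        return 0.0
    return float(dot / norm)


def annotate_features(
    features: FeatureTable,
    library: SpectralLibrary,
    ms1_tol: float = 0.01,
    ms2_tol: float = 0.015,
    rt_tol: float = 0.4,
    min_ms2_similarity: float = 0.7,
) -> pd.DataFrame:
    """Best library match per feature under the tolerance cascade.

    Returns one row per feature: compound_id (or None), match_level,
    mass_error_da, rt_error_min, ms2_similarity (NaN when no MS2 on
    either side). Shrinking any tolerance never gains a match.
    """
    if min(ms1_tol, ms2_tol, rt_tol) <= 0:
        raise ValueError("tolerances must be positive")
    lib = library.table
    if lib.empty:
        raise DataError("empty spectral library")
    for spec in features.spectra.values():
        if np.any(np.asarray(spec, dtype=float)[:, 1] < 0):
            raise DataError("negative peak intensity in feature spectra")

    records = []
    for _, feat in features.table.iterrows():
        fid = feat["feature_id"]
        fspec = features.spectra.get(fid)
        candidates = []
        same_mode = lib[lib["mode"] == feat["mode"]]
        close = same_mode[(same_mode["mz"] - feat["mz"]).abs() <= ms1_tol]
        for _, entry in close.iterrows():
            mass_err = abs(entry["mz"] - feat["mz"])
            rt_known = pd.notna(entry.get("rt"))
            rt_err = abs(entry["rt"] - feat["rt"]) if rt_known else np.nan
            if rt_known and rt_err > rt_tol:
                continue
            lspec = library.spectra.get(entry["compound_id"])
            sim = np.nan
            if fspec is not None and lspec is not None:
                sim = ms2_cosine(fspec, lspec, ms2_tol=ms2_tol)
                if sim < min_ms2_similarity:
                    continue
            if rt_known and not np.isnan(sim):
                level = "ms1_rt_ms2"
            elif rt_known:
                level = "ms1_rt"
            else:
                level = "ms1_only"
            candidates.append(
                (
                    -_LEVEL_RANK[level],
                    -(0.0 if np.isnan(sim) else sim),
                    mass_err,
                    str(entry["compound_id"]),
                    level,
                    rt_err,
                    sim,
                )
            )
        if candidates:
            best = min(candidates)
            records.append(
                {
                    "feature_id": fid,
                    "compound_id": best[3],
                    "match_level": best[4],
                    "mass_error_da": best[2],
                    "rt_error_min": best[5],
                    "ms2_similarity": best[6],
                }
            )
        else:
            records.append(
                {
                    "feature_id": fid,
                    "compound_id": None,
                    "match_level": None,
                    "mass_error_da": np.nan,
                    "rt_error_min": np.nan,
                    "ms2_similarity": np.nan,
                }
            )
    return pd.DataFrame(records).set_index("feature_id")


def class_summary(
    annotations: pd.DataFrame, taxonomy: dict, min_class_size: int = 3
) -> pd.Series:
    """Distinct annotated metabolites per chemical class.

    ``taxonomy`` maps compound id -> class label (a provided
    classification column, not computed here). Compounds missing from the
    taxonomy count under "unclassified" with a warning; classes with
    fewer than ``min_class_size`` metabolites are dropped.
    """
    matched = annotations["compound_id"].dropna().unique()
    unknown = [c for c in matched if c not in taxonomy]
    if unknown:
        warnings.warn(f"{len(unknown)} annotated compounds missing from the taxonomy")
    classes = pd.Series({c: taxonomy.get(c, "unclassified") for c in matched})
    counts = classes.value_counts()
    return counts[counts >= min_class_size].sort_index()
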