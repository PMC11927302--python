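"""MS2 cosine, tolerance-cascade annotation, and chemical-class summaries."""

import numpy as np
import pandas as pd
import pytest

from fluiddeconv.errors import DataError
from fluiddeconv.metabolome import annotate_features, class_summary, ms2_cosine
from fluiddeconv.synthetic import (
    FeatureTable,
    SpectralLibrary,
    make_metabolite_pathways,
    simulate_metabolome,
)


def spec(*peaks):
    return np.array(peaks, dtype=float)


# ------------------------------------------------------------------ cosine

def test_cosine_identical_spectra_is_one():
    s = spec((100.0, 50.0), (150.0, 10.0), (200.2, 80.0))
    assert ms2_cosine(s, s) == pytest.approx(1.0)


def test_cosine_disjoint_masses_is_zero():
    a = spec((100.0, 50.0), (150.0, 10.0))
    b = spec((120.0, 50.0), (170.0, 10.0))
    assert ms2_cosine(a, b) == 0.0


def test_cosine_hand_computed_three_peak_example():
    a = spec((100.0, 4.0), (150.0, 9.0), (200.0, 16.0))
    b = spec((100.0, 1.0), (150.0, 4.0), (250.0, 25.0))
    # pairs: (4,1) and (9,4); sqrt-intensity dot = 2*1 + 3*2 = 8
    # norms: sqrt(4+9+16)=sqrt(29), sqrt(1+4+25)=sqrt(30)
    assert ms2_cosine(a, b) == pytest.approx(8.0 / np.sqrt(29 * 30))


def test_cosine_is_symmetric_and_rejects_bad_spectra():
    a = spec((100.0, 4.0), (101.0, 9.0))
    b = spec((100.005, 1.0), (101.2, 4.0))
    assert ms2_cosine(a, b) == pytest.approx(ms2_cosine(b, a))
    with pytest.raises(ValueError):
        ms2_cosine(np.empty((0, 2)), a)
    with pytest.raises(DataError):
        ms2_cosine(spec((100.0, -1.0)), a)


def test_cosine_agrees_with_matchms_on_unambiguous_spectra():
    matchms = pytest.importorskip("matchms")
    from matchms import Spectrum
    from matchms.similarity import CosineGreedy

    rng = np.random.default_rng(3)
    mz_a = np.sort(rng.uniform(100, 500, 8))
    mz_b = mz_a + rng.uniform(-0.005, 0.005, 8)  # well-separated, unique pairing
    ia, ib = rng.uniform(1, 100, 8), rng.uniform(1, 100, 8)
    ours = ms2_cosine(np.column_stack([mz_a, ia]), np.column_stack([mz_b, ib]))
    # sqrt-intensity cosine == plain cosine on sqrt-transformed spectra
    sa = Spectrum(mz=mz_a, intensities=np.sqrt(ia), metadata_harmonization=False)
    sb = Spectrum(mz=mz_b, intensities=np.sqrt(ib), metadata_harmonization=False)
    ref = CosineGreedy(tolerance=0.015).pair(sa, sb)
    assert ours == pytest.approx(float(ref["score"]), abs=1e-9)


# ------------------------------------------------------------------ annotation

def tiny_library():
    table = pd.DataFrame(
        [
            {"compound_id": "noRT", "mode": "pos", "mz": 180.063, "rt": np.nan,
             "inchikey": "K1", "chemical_class": "sugar"},
            {"compound_id": "withRT", "mode": "pos", "mz": 200.100, "rt": 5.0,
             "inchikey": "K2", "chemical_class": "amine"},
            {"compound_id": "negmode", "mode": "neg", "mz": 300.050, "rt": 2.0,
             "inchikey": "K3", "chemical_class": "acid"},
        ]
    )
    return SpectralLibrary(table=table, spectra={})


def features_of(rows, spectra=None):
    df = pd.DataFrame(rows)
    df["S01"] = 1.0
    return FeatureTable(table=df, spectra=spectra or {})


def test_ms1_within_tolerance_without_library_rt_matches():
    feats = features_of(
        [{"feature_id": "f1", "mode": "pos", "mz": 180.063 + 0.0065, "rt": 9.9}]
    )
    ann = annotate_features(feats, tiny_library())
    assert ann.loc["f1", "compound_id"] == "noRT"
    assert ann.loc["f1", "match_level"] == "ms1_only"
    assert ann.loc["f1", "mass_error_da"] == pytest.approx(0.0065)


def test_rt_beyond_tolerance_rejects_known_rt_entry():
    feats = features_of(
        [{"feature_id": "f1", "mode": "pos", "mz": 200.100, "rt": 5.5}]
    )
    ann = annotate_features(feats, tiny_library())
    assert ann.loc["f1", "compound_id"] is None
    within = features_of([{"feature_id": "f2", "mode": "pos", "mz": 200.100, "rt": 5.35}])
    ann2 = annotate_features(within, tiny_library())
    assert ann2.loc["f2", "compound_id"] == "withRT"
    assert ann2.loc["f2", "match_level"] == "ms1_rt"


def test_modes_are_never_cross_matched():
    feats = features_of([{"feature_id": "f1", "mode": "pos", "mz": 300.050, "rt": 2.0}])
    ann = annotate_features(feats, tiny_library())
    assert ann.loc["f1", "compound_id"] is None


def test_matching_ms2_upgrades_level_and_failing_ms2_rejects():
    ref = spec((90.0, 10.0), (120.0, 40.0), (150.0, 30.0))
    lib = tiny_library()
    lib.spectra["withRT"] = ref
    good = features_of(
        [{"feature_id": "f1", "mode": "pos", "mz": 200.100, "rt": 5.0}], {"f1": ref.copy()}
    )
    ann = annotate_features(good, lib)
    assert ann.loc["f1", "match_level"] == "ms1_rt_ms2"
    assert ann.loc["f1", "ms2_similarity"] == pytest.approx(1.0)
    shifted = ref.copy()
    shifted[:, 0] += 0.02  # beyond the 0.015 Da fragment tolerance
    bad = features_of(
        [{"feature_id": "f1", "mode": "pos", "mz": 200.100, "rt": 5.0}], {"f1": shifted}
    )
    assert annotate_features(bad, lib).loc["f1", "compound_id"] is None


def test_annotation_order_independent_and_tie_broken_by_mass_then_id():
    table = pd.DataFrame(
        [
            {"compound_id": "b_far", "mode": "pos", "mz": 100.008, "rt": np.nan,
             "inchikey": "K", "chemical_class": "c"},
            {"compound_id": "a_near", "mode": "pos", "mz": 100.002, "rt": np.nan,
             "inchikey": "K", "chemical_class": "c"},
        ]
    )
    feats = features_of([{"feature_id": "f1", "mode": "pos", "mz": 100.000, "rt": 1.0}])
    lib = SpectralLibrary(table=table, spectra={})
    flipped = SpectralLibrary(table=table.iloc[::-1].reset_index(drop=True), spectra={})
    a1 = annotate_features(feats, lib)
    a2 = annotate_features(feats, flipped)
    assert a1.loc["f1", "compound_id"] == a2.loc["f1", "compound_id"] == "a_near"


def test_synthetic_truth_recovered_and_decoys_rejected():
    pathways = make_metabolite_pathways([f"pw{i}" for i in range(5)], seed=1)
    feats, lib, truth = simulate_metabolome(pathways, ["pw0", "pw1"], n_features=80,
                                            n_decoys=9, seed=5)
    ann = annotate_features(feats, lib)
    for fid, expected in truth.items():
        got = ann.loc[fid, "compound_id"]
        if expected is None:
            assert got is None or got != got  # None or NaN
        else:
            assert got == expected


def test_shrinking_tolerances_never_adds_matches():
    pathways = make_metabolite_pathways([f"pw{i}" for i in range(4)], seed=2)
    feats, lib, _ = simulate_metabolome(pathways, ["pw0"], n_features=60, n_decoys=6, seed=6)
    wide = annotate_features(feats, lib, ms1_tol=0.01, rt_tol=0.4)
    narrow = annotate_features(feats, lib, ms1_tol=0.002, rt_tol=0.04)
    wide_matched = set(wide.index[wide["compound_id"].notna()])
    narrow_matched = set(narrow.index[narrow["compound_id"].notna()])
    assert narrow_matched <= wide_matched


# ------------------------------------------------------------------ class summary

def test_class_summary_threshold_and_unclassified():
    ann = pd.DataFrame(
        {"compound_id": ["c1", "c2", "c3", "c4", "c5", None, "c6"]},
        index=[f"f{i}" for i in range(7)],
    )
    taxonomy = {"c1": "amino", "c2": "amino", "c3": "amino", "c4": "lipid", "c5": "lipid"}
    with pytest.warns(UserWarning, match="taxonomy"):
        summary = class_summary(ann, taxonomy)
    assert summary["amino"] == 3
    assert "lipid" not in summary  # only 2 members
    assert "unclassified" not in summary  # single orphan falls under the threshold
    assert class_summary(ann.iloc[:0], taxonomy).empty
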