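"""Covariate-adjusted OLS differential expression and bootstrap CIs."""

import numpy as np
import pandas as pd
import pytest

from fluiddeconv.de import bootstrap_logfc_ci, build_design, default_filter, fit_de
from fluiddeconv.errors import DataError, DesignError


def two_fold_fixture(n_per_class=4, scale=1):
    """Zero-noise cohort: one gene exactly doubled in class B, equal library sizes."""
    genes = [f"bal{i}" for i in range(40)] + ["g_eff"]
    a_col = np.array([1000 * scale] * 40 + [100 * scale])
    b_col = a_col.copy()
    b_col[-1] = 200 * scale
    b_col[0] -= 100 * scale  # keep totals identical
    cols = {f"a{i}": a_col for i in range(n_per_class)}
    cols.update({f"b{i}": b_col for i in range(n_per_class)})
    counts = pd.DataFrame(cols, index=genes)
    labels = pd.Series(
        ["A"] * n_per_class + ["B"] * n_per_class, index=counts.columns
    )
    return counts, labels


def test_constructed_two_fold_effect_yields_unit_log2fc():
    counts, labels = two_fold_fixture(scale=100)
    res = fit_de(counts, labels)
    assert res.loc["g_eff", "log2fc"] == pytest.approx(1.0, abs=0.05)
    assert res.loc["g_eff", "p_adj"] < 0.05 and res.loc["g_eff", "significant"]


def test_label_swap_negates_logfc_and_keeps_p():
    rng = np.random.default_rng(2)
    counts = pd.DataFrame(
        rng.poisson(100, size=(30, 8)),
        index=[f"g{i}" for i in range(30)],
        columns=[f"s{j}" for j in range(8)],
    )
    labels = pd.Series(["A"] * 4 + ["B"] * 4, index=counts.columns)
    flipped = labels.map({"A": "Z", "B": "A"})  # swaps which class is second
    r1 = fit_de(counts, labels, filter_spec=None)
    r2 = fit_de(counts, flipped, filter_spec=None)
    np.testing.assert_allclose(r1["log2fc"], -r2["log2fc"].reindex(r1.index), atol=1e-12)
    np.testing.assert_allclose(r1["p_raw"], r2["p_raw"].reindex(r1.index), atol=1e-12)


def test_collinear_design_is_named():
    labels = pd.Series(["A", "A", "B", "B"], index=list("wxyz"))
    cov = pd.DataFrame({"creatinine_mg_dl": [0.0, 0.0, 1.0, 1.0]}, index=list("wxyz"))
    with pytest.raises(DesignError, match="creatinine"):
        build_design(labels, cov)
    const = pd.DataFrame({"volume_ml": [5.0] * 4}, index=list("wxyz"))
    with pytest.raises(DesignError, match="volume|intercept"):
        build_design(labels, const)


def test_missing_covariate_is_data_error():
    labels = pd.Series(["A", "A", "B", "B"], index=list("wxyz"))
    cov = pd.DataFrame({"creatinine_mg_dl": [1.0, np.nan, 2.0, 3.0]}, index=list("wxyz"))
    with pytest.raises(DataError, match="x"):
        build_design(labels, cov)


def test_confound_absorbed_by_covariate_adjustment():
    """A gene driven purely by creatinine, which itself differs by class,
    shows a class effect unadjusted but ~0 after adjustment."""
    rng = np.random.default_rng(7)
    n = 12
    labels = pd.Series(["A"] * n + ["B"] * n, index=[f"s{i}" for i in range(2 * n)])
    creat = np.concatenate([rng.uniform(40, 60, n), rng.uniform(140, 160, n)])
    cov = pd.DataFrame({"creatinine_mg_dl": creat}, index=labels.index)
    base = rng.poisson(500, size=(50, 2 * n)).astype(float)
    # confounded gene: log-linear in creatinine, no class effect of its own
    base[0] = 2.0 ** (6.0 + creat / 40.0) * rng.lognormal(0.0, 0.05, 2 * n)
    counts = pd.DataFrame(
        np.rint(base).astype(int), index=[f"g{i}" for i in range(50)], columns=labels.index
    )
    unadj = fit_de(counts, labels, filter_spec=None, use_tmm=False)
    adj = fit_de(counts, labels, covariates=cov, filter_spec=None, use_tmm=False)
    assert abs(unadj.loc["g0", "log2fc"]) > 5 * abs(adj.loc["g0", "log2fc"])
    assert adj.loc["g0", "p_raw"] > 0.05


def test_default_filter_requires_cpm_in_min_class():
    counts = pd.DataFrame(
        {"a1": [0, 100], "a2": [0, 100], "b1": [100, 100], "b2": [100, 100], "b3": [100, 100]},
        index=["sparse", "dense"],
    )
    labels = pd.Series(["A", "A", "B", "B", "B"], index=counts.columns)
    kept = default_filter(counts, labels)
    assert "dense" in kept.index and "sparse" in kept.index  # 3 samples >= min(2,3)
    counts.loc["sparse", ["b2", "b3"]] = 0
    assert "sparse" not in default_filter(counts, labels).index


def test_bootstrap_ci_zero_noise_brackets_unit_logfc():
    counts, labels = two_fold_fixture(scale=100)
    ci = bootstrap_logfc_ci(counts, labels, ["g_eff"], n_boot=200, seed=0)
    row = ci.loc["g_eff"]
    # the whole interval sits within the 1.0 +/- 0.05 effect tolerance
    assert row["ci_low"] == pytest.approx(1.0, abs=0.05)
    assert row["ci_high"] == pytest.approx(1.0, abs=0.05)
    assert row["ci_high"] - row["ci_low"] < 0.1
    assert row["ci_low"] <= row["log2fc"] <= row["ci_high"]


def test_bootstrap_ci_is_seed_deterministic():
    rng = np.random.default_rng(4)
    counts = pd.DataFrame(
        rng.poisson(200, size=(25, 10)),
        index=[f"g{i}" for i in range(25)],
        columns=[f"s{j}" for j in range(10)],
    )
    labels = pd.Series(["A"] * 5 + ["B"] * 5, index=counts.columns)
    c1 = bootstrap_logfc_ci(counts, labels, ["g3"], n_boot=120, seed=9)
    c2 = bootstrap_logfc_ci(counts, labels, ["g3"], n_boot=120, seed=9)
    pd.testing.assert_frame_equal(c1, c2)
    assert c1.loc["g3", "ci_low"] <= c1.loc["g3", "log2fc"] <= c1.loc["g3", "ci_high"]
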