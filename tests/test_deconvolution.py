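"""NNLS deconvolution, zeroing rule, bootstrap CIs and group comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from fluiddeconv.basis import pseudobulk
from fluiddeconv.deconvolution import (
    FractionTable,
    compare_groups,
    deconvolve,
    fraction_ci,
    zero_small_fractions,
)
from fluiddeconv.errors import DataError
from fluiddeconv.synthetic import make_reference, simulate_bulk_cohort


@pytest.fixture(scope="module")
def basis(small_atlas):
    return pseudobulk(small_atlas)


def as_bulk(vec, basis, name="s"):
    return pd.DataFrame({name: vec}, index=basis.index)


def test_pure_column_recovers_unit_fraction(basis):
    ft = deconvolve(as_bulk(basis.iloc[:, 1], basis), basis)
    expected = np.zeros(basis.shape[1])
    expected[1] = 1.0
    np.testing.assert_allclose(ft.fractions.iloc[0], expected, atol=1e-8)


def test_noiseless_mixture_recovers_weights(basis):
    mix = 0.3 * basis.iloc[:, 0] + 0.7 * basis.iloc[:, 1]
    ft = deconvolve(as_bulk(mix, basis), basis)
    np.testing.assert_allclose(
        ft.fractions.iloc[0], [0.3, 0.7, 0.0], atol=1e-6
    )


def test_bulk_scale_invariance(basis):
    mix = 0.2 * basis.iloc[:, 0] + 0.8 * basis.iloc[:, 2]
    a = deconvolve(as_bulk(mix, basis), basis).fractions
    b = deconvolve(as_bulk(mix * 1234.5, basis), basis).fractions
    np.testing.assert_allclose(a, b, atol=1e-10)


def test_no_shared_genes_is_data_error(basis):
    bulk = pd.DataFrame({"s": [1.0, 2.0]}, index=["zz1", "zz2"])
    with pytest.raises(DataError, match="shared"):
        deconvolve(bulk, basis)


def test_recovery_error_nonincreasing_in_depth():
    """Spearman correlation between depth and recovery MAE is <= 0 over a
    depth grid, 20 seeded cohorts."""
    atlas = make_reference(4, 200, 25, 10, seed=30)
    basis = pseudobulk(atlas)
    depths = [1e4, 1e5, 1e6]
    maes = {d: [] for d in depths}
    for seed in range(20):
        for d in depths:
            counts, truth = simulate_bulk_cohort(
                atlas, (1, 1), depth_range=(d, d), concentration=5.0, seed=seed
            )
            ft = deconvolve(counts, basis)
            err = np.abs(
                ft.fractions.to_numpy() - truth.true_fractions.to_numpy()
            ).mean()
            maes[d].append(err)
    mean_mae = [np.mean(maes[d]) for d in depths]
    rho, _ = sps.spearmanr(depths, mean_mae)
    assert rho <= 0


def test_zeroing_is_strictly_below_threshold():
    fr = pd.DataFrame(
        {"t1": [0.0009, 0.0010], "t2": [0.9991, 0.9990]}, index=["s1", "s2"]
    )
    ft = FractionTable(fr, pd.Series([0.0, 0.0], index=fr.index))
    z = zero_small_fractions(ft)
    assert z.fractions.loc["s1", "t1"] == 0.0
    assert z.fractions.loc["s2", "t1"] == 0.0010  # kept: not strictly below
    # not renormalized and idempotent
    assert z.fractions.loc["s1", "t2"] == 0.9991
    pd.testing.assert_frame_equal(zero_small_fractions(z).fractions, z.fractions)


def test_all_zero_rows_are_excluded_from_comparison():
    cols = ["t1", "t2"]
    fa = pd.DataFrame([[0.4, 0.6]] * 3 + [[0.0, 0.0]], columns=cols)
    fb = pd.DataFrame([[0.7, 0.3]] * 3, columns=cols)
    fb.index = [f"b{i}" for i in range(3)]
    res = compare_groups(
        FractionTable(fa, pd.Series(0.0, index=fa.index)),
        FractionTable(fb, pd.Series(0.0, index=fb.index)),
    )
    assert (res["n_nonzero"] <= 6).all()  # the all-zero sample never counted


def test_fraction_ci_noiseless_is_tight_and_seeded(basis):
    mix = 0.4 * basis.iloc[:, 0] + 0.6 * basis.iloc[:, 2]
    sample = pd.Series(mix, index=basis.index, name="s")
    ci = fraction_ci(sample, basis, n_boot=200, seed=1)
    assert ((ci["ci_high"] - ci["ci_low"]) < 0.01).all()
    assert ((ci["ci_low"] <= ci["fraction"]) & (ci["fraction"] <= ci["ci_high"])).all()
    pd.testing.assert_frame_equal(ci, fraction_ci(sample, basis, n_boot=200, seed=1))
    assert not ci.equals(fraction_ci(sample, basis, n_boot=200, seed=2))


def _fraction_table(values, prefix):
    fr = pd.DataFrame(values, columns=["t_test", "t_ref"])
    fr.index = [f"{prefix}{i}" for i in range(len(fr))]
    return FractionTable(fr, pd.Series(0.0, index=fr.index))


def test_inclusion_rule_cohort_shape_6_vs_12():
    """With n_A=6, n_B=12 the threshold is 6/18 nonzero: a cell type seen in
    5 samples is skipped, in 6 it is tested."""
    rng = np.random.default_rng(0)

    def build(n_nonzero):
        vals_a = [[0.5 if i < min(n_nonzero, 6) else 0.0, 0.5] for i in range(6)]
        used = min(n_nonzero, 6)
        vals_b = [
            [0.5 if i < n_nonzero - used else 0.0, 0.5] for i in range(12)
        ]
        # jitter the reference column so ranks are informative
        a = _fraction_table(vals_a, "a")
        b = _fraction_table(vals_b, "b")
        a.fractions["t_ref"] += rng.uniform(0, 0.01, 6)
        b.fractions["t_ref"] += rng.uniform(0, 0.01, 12)
        return a, b

    skipped = compare_groups(*build(5))
    tested = compare_groups(*build(6))
    assert not skipped.loc["t_test", "tested"]
    assert np.isnan(skipped.loc["t_test", "p_raw"])
    assert tested.loc["t_test", "tested"]
    assert tested.loc["t_test", "p_raw"] <= 1.0


def test_compare_groups_exact_small_sample_p():
    a = _fraction_table([[0.1, 0.9], [0.2, 0.8]], "a")
    b = _fraction_table([[0.3, 0.7], [0.4, 0.6]], "b")
    res = compare_groups(a, b)
    assert res.loc["t_test", "p_raw"] == pytest.approx(1 / 3)


def test_compare_groups_identical_groups_adjusted_p_one():
    a = _fraction_table([[0.5, 0.5]] * 3, "a")
    b = _fraction_table([[0.5, 0.5]] * 3, "b")
    res = compare_groups(a, b)
    assert (res.loc[res["tested"], "p_adj"] == 1.0).all()


def test_compare_groups_needs_two_per_group():
    a = _fraction_table([[0.5, 0.5]], "a")
    b = _fraction_table([[0.5, 0.5]] * 3, "b")
    with pytest.raises(ValueError):
        compare_groups(a, b)


def test_nusvr_solver_approximates_mixture(basis):
    mix = 0.3 * basis.iloc[:, 0] + 0.7 * basis.iloc[:, 1]
    ft = deconvolve(as_bulk(mix, basis), basis, method="nu-svr")
    assert ft.fractions.iloc[0].idxmax() == basis.columns[1]
    np.testing.assert_allclose(ft.fractions.iloc[0].sum(), 1.0, atol=1e-9)
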