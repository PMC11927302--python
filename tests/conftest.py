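import numpy as np
import pandas as pd
import pytest

from fluiddeconv.synthetic import make_reference, simulate_bulk_cohort


@pytest.fixture(scope="session")
def small_atlas():
    return make_reference(
        n_cell_types=3, n_genes=120, cells_per_type=20, marker_genes_per_type=8, seed=11
    )


@pytest.fixture(scope="session")
def small_cohort(small_atlas):
    return simulate_bulk_cohort(
        small_atlas, n_samples_per_group=(4, 4), depth_range=(2e5, 4e5), seed=12
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def make_counts(rng, n_genes=60, n_samples=6, lam=50.0):
    """Random Poisson count matrix helper."""
    mat = rng.poisson(lam, size=(n_genes, n_samples))
    return pd.DataFrame(
        mat,
        index=[f"g{i:03d}" for i in range(n_genes)],
        columns=[f"s{j}" for j in range(n_samples)],
    )
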