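import numpy as np
import pandas as pd
import pytest

from mgwas.simulate import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_null_cohort():
    """A null cohort (no planted effects) shared by read-only tests."""
    return simulate_cohort(
        SimConfig(n_samples=300, n_variants=200, n_taxa=15, fst=0.0, seed=42)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_covariates(rng):
    n = 30
    return pd.DataFrame(
        {"age": rng.normal(30, 5, n), "sex": rng.binomial(1, 0.5, n).astype(float)},
        index=[f"S{i:05d}" for i in range(n)],
    )
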