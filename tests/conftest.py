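import numpy as np
import pytest

from meqtlkit.pipeline import synthetic_study
from meqtlkit.simulate import SimConfig


@pytest.fixture(scope="session")
def small_config():
    """A light two-cohort study used by several module tests."""
    return SimConfig(
        n_cohorts=2,
        samples_per_cohort=[150, 120],
        n_snps=60,
        n_cpgs=50,
        ld_block_size=5,
        ld_rho=0.6,
        n_cis_effects=8,
        n_trans_effects=4,
        n_mz_pairs=10,
        n_dz_pairs=10,
        effect_r2=0.2,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return synthetic_study(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
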