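import numpy as np
import pytest

from cisreg.config import SimConfig
from cisreg import synthetic_data as sd


@pytest.fixture(scope="session")
def table3():
    """Subject-level expansion of the bundled genotype-count fixture."""
    return sd.table3_fixture()


@pytest.fixture(scope="session")
def small_cfg():
    return SimConfig(seed=11, n_genes=10, n_snvs=100, n_samples_per_group=15)


@pytest.fixture(scope="session")
def cohort():
    return sd.gen_cohort(SimConfig(seed=23))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
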