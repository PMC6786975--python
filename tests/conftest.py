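import numpy as np
import pytest

from genokit.simdata import SimConfig, sim_cohort, sim_reference_panel


@pytest.fixture(scope="session")
def small_panel():
    config = SimConfig(seed=11, n_sites=300, n_haplotypes=120, n_founders=15)
    return sim_reference_panel(config)


@pytest.fixture(scope="session")
def small_cohort(small_panel):
    config = SimConfig(seed=11, n_sites=300, n_haplotypes=120, n_founders=15)
    cohort, truth = sim_cohort(small_panel, 150, config)
    return cohort, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
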