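import numpy as np
import pytest

from mchron.simulate import SimConfig, generate_genome


@pytest.fixture(scope="session")
def sim_config() -> SimConfig:
    return SimConfig(seed=11)


@pytest.fixture(scope="session")
def genome(sim_config):
    return generate_genome(sim_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
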