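import numpy as np
import pytest
from hypothesis import settings

from homeoconv import SimulationConfig, simulate_dataset

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        n_chromosomes=1,
        genes_per_chromosome=60,
        codons_per_gene=60,
        gene_loss_rate=0.05,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
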