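import numpy as np
import pytest

from turnover15n import EnrichmentModel
from turnover15n.synthetic_data import SimulationConfig, generate_truth, simulate_experiment


@pytest.fixture(scope="session")
def model():
    return EnrichmentModel()


@pytest.fixture(scope="session")
def small_cfg():
    return SimulationConfig(n_proteins=12, peptides_per_protein_mean=3.0,
                            cargo_fraction=0.3, seed=11)


@pytest.fixture(scope="session")
def small_truth(small_cfg):
    return generate_truth(small_cfg)


@pytest.fixture(scope="session")
def small_observations(small_truth, small_cfg):
    return simulate_experiment(small_truth, small_cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
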