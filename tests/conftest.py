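import numpy as np
import pytest

from daughterqtl import (SimulationConfig, VarianceComponents,
                         inverse_relationship_matrix, simulate_dataset)


@pytest.fixture(scope="session")
def study_dataset():
    """Full study-scale synthetic dataset: 14 sires, 638 daughters, 13 SNPs."""
    return simulate_dataset(SimulationConfig(), seed=11)


@pytest.fixture(scope="session")
def study_a_inv(study_dataset):
    ped = study_dataset[0]
    return inverse_relationship_matrix(ped)


@pytest.fixture(scope="session")
def small_dataset():
    """Reduced-scale dataset for fast model-fitting tests."""
    config = SimulationConfig(n_sires=4, daughters_per_sire=15)
    return simulate_dataset(config, seed=7)


@pytest.fixture
def vc():
    return VarianceComponents(var_a=1.0, var_e=1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
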