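import numpy as np
import pytest

from effectome import synthetic_data as sd


@pytest.fixture(scope="session")
def small_cfg():
    return sd.SimulationConfig(seed=11, n_genes=60, n_planted_effectors=5)


@pytest.fixture(scope="session")
def small_genome(small_cfg):
    return sd.simulate_genome(small_cfg)


@pytest.fixture(scope="session")
def small_counts(small_cfg, small_genome):
    return sd.simulate_counts(small_cfg, small_genome.truth)


@pytest.fixture(scope="session")
def small_proteome(small_cfg, small_genome):
    return sd.simulate_proteome(small_cfg, small_genome.truth)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)
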