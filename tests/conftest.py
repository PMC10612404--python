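import numpy as np
import pytest
from hypothesis import settings

from ecbench.synthetic import SimParams, simulate

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_sim():
    """A modest unambiguous-mode diploid simulation shared across tests."""
    params = SimParams(genome_length=60_000, n_chromosomes=2, read_length=4_000,
                       coverage=10, error_rate=0.002, p_correct=0.8,
                       q_overcorrect=0.3, unambiguous=True, seed=42)
    return simulate(params)
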