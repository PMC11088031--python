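import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from plrex.io_cli import RunConfig
from plrex.minhash_index import HashFamily, build_index
from plrex.simeval import simulate_genome, simulate_pairs


@pytest.fixture(scope="session")
def small_sim():
    """20 kbp genome, 30x, read length 100, insert N(500, 10), 0.5% errors."""
    genome = simulate_genome(20_000, 7)
    return simulate_pairs(genome, 30.0, 100, 500.0, 10.0, (460, 540), 0.005, 8)


@pytest.fixture(scope="session")
def small_cfg():
    return RunConfig(insert_mu=500, insert_sd=10, seed=1)


@pytest.fixture(scope="session")
def small_index(small_sim, small_cfg):
    fam = HashFamily.from_seed(small_cfg.seed)
    idx = build_index(small_sim.store, fam)
    return fam, idx


@pytest.fixture(scope="session")
def noiseless_sim():
    """Error-free 12 kbp simulation for exact-recovery style checks."""
    genome = simulate_genome(12_000, 31)
    return simulate_pairs(genome, 30.0, 100, 500.0, 10.0, (460, 540), 0.0, 32)


@pytest.fixture
def rng():
    return np.random.Generator(np.random.PCG64(1234))
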