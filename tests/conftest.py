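import numpy as np
import pytest

from barmerge.simgen import SimParams, random_reference, simulate_pairs


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_ref():
    return random_reference(20_000, seed=42)


@pytest.fixture(scope="session")
def clean_sim(small_ref):
    """50 error-free simulated pairs with their ground truth."""
    params = SimParams(n_pairs=50, sub_rate_scale=0.0, indel_rate=0.0, rng_seed=7)
    return simulate_pairs(small_ref, params)


@pytest.fixture(scope="session")
def noisy_sim(small_ref):
    """200 pairs under the default error model."""
    params = SimParams(n_pairs=200, rng_seed=8)
    return simulate_pairs(small_ref, params)
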