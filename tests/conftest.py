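import numpy as np
import pytest

from nichesim import GenotypeSpace, ModelParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def space_l3():
    return GenotypeSpace(L=3, B=1)


@pytest.fixture
def space_l5():
    return GenotypeSpace(L=5, B=1)


@pytest.fixture
def small_params():
    """Small, fast configuration for engine-level tests."""
    return ModelParams(L=3, s=0.1, fitness_model="additive", r=1e-3, K=2000,
                       max_generations=200, seed=7)


@pytest.fixture
def paper_params():
    """Standard demography (R=1, b_max=10, d=0.1, K=1e6)."""
    return ModelParams(L=5, s=0.01, fitness_model="additive", r=1e-4)
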