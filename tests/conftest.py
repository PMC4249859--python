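import numpy as np
import pytest

from ephsim.core_model import InteractionParams, PopulationParams
from ephsim.simulator import Domain


@pytest.fixture
def default_params() -> PopulationParams:
    """The canonical interaction parameter set (R=250, A=100, r=5.8, a=7.5)."""
    return PopulationParams(R=250.0, A=100.0, r=5.8, a=7.5)


@pytest.fixture
def compact_params() -> PopulationParams:
    """Reduced surface tension (R=220) of the enhanced-signalling Eph cells."""
    return PopulationParams(R=220.0, A=100.0, r=5.8, a=7.5)


@pytest.fixture
def interaction(default_params) -> InteractionParams:
    return InteractionParams(eph=default_params, ephrin=default_params, C=1.0)


@pytest.fixture
def domain() -> Domain:
    return Domain(width=640.0, height=640.0, boundary="REFLECTING")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_population_params(rng: np.random.Generator) -> PopulationParams:
    """Random valid parameter set with a guaranteed equilibrium (R·a > A·r)."""
    r = rng.uniform(2.0, 8.0)
    a = r * rng.uniform(1.1, 2.5)
    A = rng.uniform(10.0, 200.0)
    R = A * (r / a) * rng.uniform(1.5, 5.0)
    return PopulationParams(R=R, A=A, r=r, a=a)
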