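import numpy as np
import pytest

from quorumevo.core_dynamics import DynamicsParams, SignalEnvironment
from quorumevo.fitness import PayoffParams, build_density_grid


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def default_grid():
    return build_density_grid()


@pytest.fixture
def env():
    return SignalEnvironment(N=5.0016e4, u=1e-4)


@pytest.fixture
def dyn():
    return DynamicsParams()


@pytest.fixture
def pay():
    return PayoffParams()
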