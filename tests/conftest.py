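import numpy as np
import pytest

from poroident import (BiphasicParameters, Environment, Grid1D, ParameterSpace,
                       Protocol)


@pytest.fixture(scope="session")
def space():
    return ParameterSpace.default()


@pytest.fixture(scope="session")
def env():
    return Environment()


@pytest.fixture(scope="session")
def midpoint_params(space):
    return BiphasicParameters.midpoint(space)


@pytest.fixture(scope="session")
def uncharged_params(midpoint_params):
    """Midpoint parameters with osmotic swelling switched off."""
    return midpoint_params.replace(fcd0=0.0, f0=0.0)


@pytest.fixture(scope="session")
def linear_params():
    """Near-linear regime: tiny elastic nonlinearity, constant permeability."""
    return BiphasicParameters(E=300.0, nu=0.0, beta=0.04, k0=1.05e-3, M=0.0,
                              alpha=0.0, phi_w0=0.735, fcd0=0.0, Phi=0.95,
                              f0=0.0)


@pytest.fixture(scope="session")
def default_protocol():
    return Protocol()


@pytest.fixture(scope="session")
def coarse_grid():
    return Grid1D(11)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
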