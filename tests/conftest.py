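import numpy as np
import pytest

from adjfit import (
    ExperimentData,
    SolverSettings,
    compile_model,
    generate_data,
    make_fixture,
)
from adjfit.fixtures import TRANSFECTION_THETA


@pytest.fixture(scope="session")
def const_cm():
    return compile_model(make_fixture("const"))


@pytest.fixture(scope="session")
def decay_cm():
    return compile_model(make_fixture("decay"))


@pytest.fixture(scope="session")
def transfection_cm():
    return compile_model(make_fixture("transfection"))


@pytest.fixture(scope="session")
def const_data():
    """The canonical two-point dataset: ybar = {1, 3} at t = {1, 2}, sigma 1.

    At theta = 1 the objective is J = 1/2 (0^2 + 2^2) = 2 and dJ/dtheta = -2.
    """
    return ExperimentData(times=[1.0, 2.0], values=[[1.0, 3.0]], sigmas=1.0)


@pytest.fixture(scope="session")
def decay_datum():
    """Single datum ybar = 0.5 at t = ln 2; at theta = (1, 2) the analytic
    gradient is (-log(2)/2, 1/4) = (-0.34657..., 0.25)."""
    return ExperimentData(times=[np.log(2.0)], values=[[0.5]], sigmas=1.0)


@pytest.fixture(scope="session")
def transfection_theta():
    return TRANSFECTION_THETA.copy()


@pytest.fixture(scope="session")
def transfection_noisy(transfection_cm, transfection_theta):
    times = np.linspace(0.0, 10.0, 11)
    return generate_data(
        transfection_cm, transfection_theta, times, sigma=0.1, seed=0
    )


@pytest.fixture(scope="session")
def default_settings():
    return SolverSettings()
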