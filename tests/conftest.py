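import numpy as np
import pytest

from ontoradiate import ModelParameters, ResourceEnvironment, solve_equilibrium
from ontoradiate.ecology import set_parameter


@pytest.fixture(scope="session")
def params():
    return ModelParameters()


@pytest.fixture(scope="session")
def params_low():
    return set_parameter(ModelParameters(), "supply_s", 0.025)


@pytest.fixture(scope="session")
def params_high():
    return set_parameter(ModelParameters(), "supply_s", 0.2)


@pytest.fixture(scope="session")
def pristine(params):
    return ResourceEnvironment.pristine(params)


@pytest.fixture(scope="session")
def eq_high(params_high):
    """Monomorphic resident at theta_1 under high shared-resource supply."""
    return solve_equilibrium([1.0], params_high)


@pytest.fixture(scope="session")
def eq_low(params_low):
    return solve_equilibrium([1.0], params_low)
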