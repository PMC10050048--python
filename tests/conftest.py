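import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")

from mndopt.fixtures import fixture_molecule
from mndopt.params import load_packaged_parameters
from mndopt.scf import scf_solve


@pytest.fixture(scope="session")
def mndo_params():
    return load_packaged_parameters("mndo")


@pytest.fixture(scope="session")
def water(mndo_params):
    return scf_solve(fixture_molecule("H2O"), mndo_params)


@pytest.fixture(scope="session")
def methane(mndo_params):
    return scf_solve(fixture_molecule("CH4"), mndo_params)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
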