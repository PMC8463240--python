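import pytest

from qamskit import chromsim, fixtures
from qamskit.peaktable import RunConditions


@pytest.fixture(scope="session")
def ccd_design():
    return fixtures.ccd_design()


@pytest.fixture(scope="session")
def pbd_design():
    return fixtures.pbd_design()


@pytest.fixture(scope="session")
def standards():
    return fixtures.default_standards()


@pytest.fixture(scope="session")
def prep():
    return fixtures.default_sample_prep()


@pytest.fixture()
def quiet_model():
    """Noise-free simulator."""
    return chromsim.default_model(noise_cv=0.0)


@pytest.fixture()
def noisy_model():
    return chromsim.default_model(noise_cv=0.01)


@pytest.fixture()
def optimum_conditions():
    return RunConditions(methanol_fraction=60.0, column_temperature=30.0)
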