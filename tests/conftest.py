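import pytest
from hypothesis import settings

from fuelbudget import EnergyConstants, load_profile

settings.register_profile("ci", derandomize=True, max_examples=100)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def male():
    return load_profile("male")


@pytest.fixture(scope="session")
def female():
    return load_profile("female")


@pytest.fixture(scope="session")
def constants():
    return EnergyConstants()
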