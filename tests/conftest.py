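import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hydrogap.config import demo_species_path
from hydrogap.forest import load_species_table
from hydrogap.hydrology import CanopyHydroParams, EnergyParams, SoilParams
from hydrogap.weather import default_climate

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def climate():
    return default_climate()


@pytest.fixture(scope="session")
def soil():
    return SoilParams()


@pytest.fixture(scope="session")
def canopy():
    return CanopyHydroParams()


@pytest.fixture(scope="session")
def energy():
    return EnergyParams()


@pytest.fixture(scope="session")
def species_table():
    return load_species_table(demo_species_path())


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
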