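import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

from climdamage import (ClimateParams, generate_scenario_set,
                        sample_climate_params, synth_damage_registry)


@pytest.fixture(scope="session")
def small_set():
    """Five synthetic scenarios, fixed seed."""
    return generate_scenario_set(5, seed=11)


@pytest.fixture(scope="session")
def central_params():
    return ClimateParams()


@pytest.fixture(scope="session")
def registry():
    return synth_damage_registry(seed=7)


@pytest.fixture(scope="session")
def small_ensemble():
    return sample_climate_params(5, seed=13)
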