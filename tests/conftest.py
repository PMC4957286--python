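import dataclasses

import pytest
from hypothesis import HealthCheck, settings

from pacea.lifetable import default_life_table
from pacea.params import load_default_parameters

settings.register_profile(
    "suite", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def mp():
    """Bundled base-case parameters."""
    return load_default_parameters()


@pytest.fixture(scope="session")
def lt():
    """Bundled synthetic life table."""
    return default_life_table()


@pytest.fixture()
def short_horizon(mp):
    """Base-case parameters with the horizon capped at age 55 (fast runs)."""
    return dataclasses.replace(
        mp, settings=dataclasses.replace(mp.settings, max_age=55))
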