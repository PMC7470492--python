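import numpy as np
import pytest
from hypothesis import settings

from tbicea import build_base_case, bundled_age_multiplier, bundled_life_table

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def uk_params():
    return build_base_case("UK")


@pytest.fixture(scope="session")
def pk_params():
    return build_base_case("Pakistan")


@pytest.fixture(scope="session")
def uk_table():
    return bundled_life_table("UK")


@pytest.fixture(scope="session")
def pk_table():
    return bundled_life_table("Pakistan")


@pytest.fixture(scope="session")
def age_mult():
    return bundled_age_multiplier(42.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20180901)
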