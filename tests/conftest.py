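import numpy as np
import pytest
from hypothesis import settings

import swingrna as sw

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table1_profiles():
    return sw.fixture_profiles("table1")


@pytest.fixture(scope="session")
def table2_profiles():
    return sw.fixture_profiles("table2")


@pytest.fixture(scope="session")
def table4():
    return sw.load_fixture("table4").table


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
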