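import numpy as np
import pytest

from glycobo import build_default_space, load_fixture_campaign


@pytest.fixture(scope="session")
def space():
    return build_default_space()


@pytest.fixture(scope="session")
def campaign1():
    return load_fixture_campaign(1)


@pytest.fixture(scope="session")
def campaign2():
    return load_fixture_campaign(2)


@pytest.fixture(scope="session")
def campaign_all():
    return load_fixture_campaign(0)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
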