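import pytest

from collagen_cohesion.synthetic import fixture_profiles


@pytest.fixture(scope="session")
def profiles():
    """(type I, type II) composition profiles from the frozen fixtures."""
    return fixture_profiles()


@pytest.fixture(scope="session")
def type_i(profiles):
    return profiles[0]


@pytest.fixture(scope="session")
def type_ii(profiles):
    return profiles[1]
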