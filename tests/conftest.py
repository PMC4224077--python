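import pytest

import coagswitch as cs
from coagswitch.fixtures import COARSE_GRID_H, fixture_generator


@pytest.fixture(scope="session")
def network():
    return cs.get_network(cs.CAUCASIAN_MEDIAN)


@pytest.fixture(scope="session")
def japanese_network():
    return cs.get_network(cs.JAPANESE_MEDIAN)


@pytest.fixture(scope="session")
def warfarin_25(network):
    """Racemic warfarin state titrated to steady-state INR 2.5."""
    return cs.titrate_profile(network, 2.5)


@pytest.fixture(scope="session")
def coarse_corridor():
    """Start-INR 2.5 Caucasian corridor on the coarse 12-point grid."""
    return fixture_generator("corridor_small")


@pytest.fixture(scope="session")
def switch_25():
    return cs.SwitchScenario(2.5, cs.CAUCASIAN_MEDIAN, COARSE_GRID_H)
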