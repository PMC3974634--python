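import pytest

from hrtract import make_default_map
from hrtract.markers import Dsb, SimParams


@pytest.fixture
def default_map():
    return make_default_map()


@pytest.fixture
def map_with_right_half_site():
    return make_default_map(half_site="RIGHT")


@pytest.fixture
def map_with_left_half_site():
    return make_default_map(half_site="LEFT")


@pytest.fixture
def dsb_right():
    return Dsb(arm="RIGHT", position=266)


@pytest.fixture
def dsb_left():
    return Dsb(arm="LEFT", position=569)


def three_sigma_binomial(p: float, n: int) -> float:
    """3-sigma half-width for a binomial proportion estimate."""
    return 3.0 * (p * (1.0 - p) / n) ** 0.5
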