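import numpy as np
import pytest

from landcarbon.synthdata import generate_landscape
from landcarbon.world import make_world


@pytest.fixture(scope="session")
def world():
    """A small synthetic world shared by read-only tests (never mutate)."""
    return make_world(seed=42, gcms=("average",), rcps=("4.5",))


@pytest.fixture()
def forest_grid():
    """A 10x10 all-forest landscape, fresh per test (safe to mutate)."""
    return generate_landscape(10, 10, 1, {"forest": 1.0}, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
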