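import numpy as np
import pytest

from cryoss.map_io import DensityMap
from cryoss.simulate import SimulationParams, simulate_map
from cryoss.structures import build_toy_domain


@pytest.fixture(scope="session")
def toy_domain():
    """A small random mixed-class structure shared across tests."""
    return build_toy_domain(seed=7, n_elements=4)


@pytest.fixture(scope="session")
def toy_map(toy_domain):
    return simulate_map(toy_domain, SimulationParams(resolution=6.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def random_map(rng):
    return DensityMap(
        grid=rng.random((12, 10, 14)).astype(np.float32),
        origin=np.array([1.0, -2.0, 0.5]),
        spacing=np.array([1.0, 1.0, 1.0]),
    )
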