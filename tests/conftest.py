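import numpy as np
import pytest

from cytosolkit.model import SimulationCell
from cytosolkit.synthetic import BrownianSpec, gen_brownian


@pytest.fixture(scope="session")
def cell50():
    return SimulationCell.cubic(50.0)


@pytest.fixture(scope="session")
def brownian_small(cell50):
    """Modest Brownian ensemble shared by diffusion tests."""
    spec = BrownianSpec(
        counts={"A": 30},
        diffusion={"A": 0.5},
        cell=cell50,
        dt=4.0,
        n_frames=4000,
        seed=11,
    )
    return gen_brownian(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
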