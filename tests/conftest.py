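import numpy as np
import pytest

import paranet as pn
from paranet import spatial


@pytest.fixture(scope="session")
def hex_world():
    """A ~20x20 hexagon grid at the global cell size, with 200 km weights."""
    grid = pn.build_planar_hex_grid((0.0, 0.0, 3300.0, 2850.0), 23323.0)
    weights = spatial.distance_band_weights(grid.centroids(), 200.0)
    return grid, weights


@pytest.fixture(scope="session")
def design_matrix(hex_world):
    _, weights = hex_world
    rng = np.random.default_rng(987654)  # distinct from any simulation seed
    return np.column_stack([np.ones(weights.n), rng.normal(size=weights.n)])


@pytest.fixture(scope="session")
def default_fixture():
    """The default synthetic study bundle, shared across tests."""
    return pn.generate_study_fixture(pn.WorldConfig(seed=7))
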