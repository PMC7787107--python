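import numpy as np
import pytest

from emfitkit import DensityMap, SimulationParams, simulate_map
from emfitkit.fixtures import FixtureSpec, make_blob_map, make_helix_model


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_random_map(rng):
    """A fixed 3x3x3 map for hand-oracle comparisons."""
    return DensityMap(rng.random((3, 3, 3)), voxel_size=(1, 1, 1))


@pytest.fixture
def blob_map():
    density, _ = make_blob_map(FixtureSpec(seed=11, n_blobs=2))
    return density


@pytest.fixture
def helix():
    return make_helix_model(FixtureSpec(n_residues=10))


@pytest.fixture
def helix20():
    return make_helix_model(FixtureSpec(n_residues=20))


@pytest.fixture
def sim_params():
    return SimulationParams(resolution=6.0)


@pytest.fixture
def helix_map(helix, sim_params):
    return simulate_map(helix, sim_params)
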