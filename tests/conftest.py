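import numpy as np
import pytest
from shapely.geometry import box

from gapcover.synthetic import WorldConfig, generate_world


@pytest.fixture(scope="session")
def default_world():
    """The default synthetic world (seed 0), with tiers and ground truth."""
    return generate_world(WorldConfig(seed=0))


@pytest.fixture(scope="session")
def small_world_config():
    """A reduced world for fast pipeline round-trips."""
    return WorldConfig(
        n_species=24,
        n_protected=12,
        n_multiuse=2,
        min_pa_per_ecoregion=1,
        n_ecoregions=4,
        cell_size_m=250.0,
        tier_cells=80,
        seed=0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def unit_square_km():
    """A 1 km x 1 km square at the origin (coordinates in metres)."""
    return box(0.0, 0.0, 1000.0, 1000.0)
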