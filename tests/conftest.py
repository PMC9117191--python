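import numpy as np
import pytest
from shapely.geometry import Polygon

import burrowscape as bc


@pytest.fixture
def square_landscape():
    """A 200 x 200 m (4 ha) square landscape."""
    return bc.LandscapeSpec(Polygon([(0, 0), (200, 0), (200, 200), (0, 200)]))


@pytest.fixture
def small_params():
    """Modest two-species pattern for fast unit tests."""
    return bc.AvoidanceParams(
        burrow_count=25,
        mound_base_intensity=300.0,
        avoidance_radius=10.0,
        avoidance_strength=0.8,
        colony_centers=2,
        colony_spread=50.0,
        mole_patches=0,
    )


@pytest.fixture
def small_pattern(square_landscape, small_params):
    return bc.generate_point_patterns(square_landscape, small_params, seed=42)


@pytest.fixture
def zone_cfg():
    return bc.ZoneConfig(colony_kernel_radius=25.0, cell_size=1.0)
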