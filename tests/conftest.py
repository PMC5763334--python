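import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the _oracles helper

from vpsolenoid import RoiSpec, SolenoidSpec, grid_search


@pytest.fixture
def paper_spec():
    """The reference coil: 34 mm winding diameter, 3 turns, 56 mm length."""
    return SolenoidSpec()


@pytest.fixture
def coarse_spec():
    """Same coil, coarse discretization for cheap unit tests."""
    return SolenoidSpec(segments_per_turn=36)


@pytest.fixture
def tiny_roi():
    """A small ROI for fast metric tests."""
    return RoiSpec(radius_mm=6.0, z_half_extent_mm=6.0, grid_spacing_mm=2.0)


@pytest.fixture(scope="session")
def full_grid():
    """The complete 19 x 19 (alpha, beta) sweep of the reference coil at
    default discretization and ROI; shared across acceptance tests."""
    return grid_search(SolenoidSpec())
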