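import numpy as np
import pytest

from ppgsim.grid import GridSpec
from ppgsim.optical_properties import DEFAULT_SCENARIOS, MelaninSetting
from ppgsim.pulse_geometry import PulseShape, default_pulse_shape
from ppgsim.tissue_volume import VoxelGrid, build_volume, lumen_axis_depth
from ppgsim.vessel_mechanics import PressureLoad, VesselSpec


@pytest.fixture(scope="session")
def vessel():
    return VesselSpec()


@pytest.fixture(scope="session")
def load():
    return PressureLoad()


@pytest.fixture(scope="session")
def test_grid():
    """Small grid for geometry-oracle checks (same physical domain)."""
    return GridSpec(nx=70, ny=50, nz=50)


@pytest.fixture(scope="session")
def coarse_grid():
    return GridSpec.coarse()


@pytest.fixture(scope="session")
def baseline_shape(vessel):
    sc = DEFAULT_SCENARIOS[0]
    return default_pulse_shape(vessel, lumen_axis_depth_cm=lumen_axis_depth(sc, vessel))


@pytest.fixture(scope="session")
def baseline_volume(coarse_grid, baseline_shape) -> VoxelGrid:
    """BMI-25 volume at 660 nm with the envelope far outside the grid."""
    return build_volume(
        DEFAULT_SCENARIOS[0], MelaninSetting(0.0), 660, baseline_shape, 10.0,
        grid=coarse_grid,
    )


@pytest.fixture(scope="session")
def homogeneous_volume():
    """Matched-boundary homogeneous benchmark medium filling the whole grid."""
    grid = GridSpec(nx=80, ny=80, nz=60, lx_cm=1.6, ly_cm=1.6, lz_cm=1.2)
    media = np.zeros((grid.nx, grid.ny, grid.nz), dtype=np.uint8)
    props = np.array([[10.0, 90.0, 0.75, 1.0]])
    return VoxelGrid(grid=grid, media=media, properties=props)
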