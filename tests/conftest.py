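import numpy as np
import pytest

from mvoct import (
    AcqParams,
    NoiseModel,
    ScanGeometry,
    SourceSpec,
    VesselSpec,
    build_scene,
)

NOISELESS = NoiseModel(phase_jitter_sd_rad=0.0, noise_floor_db=-300.0, rolloff_db_per_mm=0.0)


@pytest.fixture(scope="session")
def acq():
    return AcqParams()


@pytest.fixture(scope="session")
def small_source():
    """512-sample source over a 2.5 mm range: same 9.77 um pitch as the default."""
    return SourceSpec(n_k=512, depth_range_mm=2.5)


@pytest.fixture(scope="session")
def flat_source():
    """Idealized flat-envelope source: leakage-free voxel <-> bin mapping."""
    return SourceSpec(n_k=512, depth_range_mm=2.5, envelope_shape="flat")


@pytest.fixture(scope="session")
def small_geometry():
    return ScanGeometry(
        fov_x_mm=1.5, fov_y_mm=0.3, depth_range_mm=2.5, n_x=300, n_z=256, n_frames=2
    )


@pytest.fixture(scope="session")
def vessel():
    return VesselSpec(
        center_x_mm=0.75,
        center_z_mm=1.25,
        radius_mm=0.25,
        peak_velocity_mm_s=10.0,
        wall_thickness_mm=0.05,
    )


@pytest.fixture(scope="session")
def flow_scene(small_geometry, vessel):
    return build_scene(small_geometry, [vessel], background_reflectivity=0.05, seed=0)
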