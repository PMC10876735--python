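import numpy as np
import pytest

from landmarknet.geometry import VoxelGeometry
from landmarknet.phantom import PhantomSpec, sample_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def geometry():
    return VoxelGeometry(in_plane_spacing=(1.5, 1.5), slice_spacing=6.0)


# tiny phantom spec for cheap rendering: 8x16x16 voxels, FOV 192 mm
TINY_TEMPLATE = (
    (30.0, 40.0, 60.0),
    (50.0, 50.0, 80.0),
    (80.0, 90.0, 50.0),
    (75.0, 70.0, 90.0),
    (80.0, 100.0, 120.0),
    (110.0, 120.0, 70.0),
    (140.0, 130.0, 100.0),
)


def tiny_spec(**overrides):
    defaults = dict(
        n_patients=3,
        n_controls=3,
        shape=(8, 16, 16),
        in_plane_spacing=(12.0, 12.0),
        slice_spacing=24.0,
        control_template_mm=TINY_TEMPLATE,
        jitter_sd_mm=3.0,
        render_radius_mm=15.0,
        noise_sd=10.0,
        seed=7,
    )
    defaults.update(overrides)
    return PhantomSpec(**defaults)


@pytest.fixture
def tiny_phantom_spec():
    return tiny_spec()


@pytest.fixture
def tiny_cohort(tiny_phantom_spec):
    return sample_cohort(tiny_phantom_spec)
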