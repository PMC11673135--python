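import numpy as np
import pytest

from regstack import RigidTransform
from regstack.imaging import mean_filter_4x4
from regstack.phantom import PhantomSpec, make_base_phantom, make_sequence


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def smooth_image():
    """Band-limited 128x128 test image (no fiducials, wide edges, no noise)."""
    spec = PhantomSpec(
        shape=(128, 128),
        blob_radius=30,
        edge_softness=8,
        texture_wavelength=20.0,
        fiducials=(),
        noise_sigma=0.0,
    )
    return make_base_phantom(spec)


@pytest.fixture(scope="session")
def small_phantom_spec():
    """Compact 128x128 phantom with mild noise for fast registration tests."""
    return PhantomSpec(shape=(128, 128), blob_radius=25, noise_sigma=5.0, rng_seed=3)


@pytest.fixture(scope="session")
def full_field_spec():
    """128x128 phantom whose textured object fills the frame (small-motion tests)."""
    return PhantomSpec.full_field(
        shape=(128, 128), blob_radius=45.0, noise_sigma=5.0, rng_seed=3
    )


@pytest.fixture(scope="session")
def full_field_frame(full_field_spec):
    seq = make_sequence(full_field_spec, [RigidTransform()])
    return mean_filter_4x4(seq.frames[0])


@pytest.fixture(scope="session")
def denoised_frame(small_phantom_spec):
    """A single denoised noisy phantom frame, the moving image of pair tests."""
    seq = make_sequence(small_phantom_spec, [RigidTransform()])
    return mean_filter_4x4(seq.frames[0])
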