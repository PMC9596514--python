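import numpy as np
import pytest

from rootvoi import PhantomSpec, generate_quadrant, reduced_phantom_spec


@pytest.fixture(scope="session")
def small_spec():
    """Fast reduced-scale phantom spec shared by pipeline-level tests."""
    return reduced_phantom_spec(shape=(48, 48, 48), voxel_size_um=20.8, crop_offset_voxels=15)


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return generate_quadrant(small_spec)


@pytest.fixture(scope="session")
def noise_free_spec():
    return PhantomSpec(
        shape=(96, 96, 96),
        air_sd=0.0,
        bone_sd=0.0,
        tooth_sd=0.0,
        heterogeneity_sd=0.0,
        blur_sigma_um=0.0,
        noise_sd=0.0,
        cej_jitter_voxels=0.0,
    )


@pytest.fixture(scope="session")
def noise_free_phantom(noise_free_spec):
    return generate_quadrant(noise_free_spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
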