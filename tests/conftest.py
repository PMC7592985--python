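import numpy as np
import pytest

from pzrad import PhantomSpec, ROIMask, VoxelVolume, generate_patient


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_volume(rng):
    """A 4-slice 16x16 random volume with anisotropic spacing."""
    return VoxelVolume(rng.normal(100.0, 10.0, (4, 16, 16)), (4.0, 1.5, 1.5))


@pytest.fixture
def full_mask(small_volume):
    return ROIMask(np.ones(small_volume.shape, dtype=bool), small_volume.spacing)


@pytest.fixture(scope="session")
def phantom_case():
    """One default-spec phantom patient, reused across read-only tests."""
    return generate_patient(PhantomSpec(seed=99), patient_seed=424242)
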