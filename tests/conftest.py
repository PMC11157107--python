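import numpy as np
import pytest

from fousr import (
    AcquisitionGeometry,
    AcquisitionSim,
    PhantomSpec,
    Volume,
    make_phantom,
    simulate_orthogonal_pair,
)

# Study-condition geometry: 1.7 mm in-plane, 5 mm slices, coronal base
# (slices along AP, axis 1) and axial donor (slices along SI, axis 2).
GEOM_CORONAL = AcquisitionGeometry(in_plane_mm=1.7, slice_mm=5.0, slice_axis=1)
GEOM_AXIAL = AcquisitionGeometry(in_plane_mm=1.7, slice_mm=5.0, slice_axis=2)


def rmse(a: Volume, b: Volume) -> float:
    return float(np.sqrt(np.mean((np.asarray(a.data) - np.asarray(b.data)) ** 2)))


def random_volume(rng: np.random.Generator, shape, spacing=(1.0, 1.0, 1.0)) -> Volume:
    return Volume(data=rng.uniform(0.0, 1.0, shape), spacing=spacing)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_phantom():
    """A 48-cube phantom with exact ROIs, shared across tests (read-only)."""
    return make_phantom(PhantomSpec(shape=(48, 48, 48), n_lesions=4, seed=7))


@pytest.fixture(scope="session")
def noiseless_pair(small_phantom):
    truth, _ = small_phantom
    return simulate_orthogonal_pair(
        truth,
        AcquisitionSim(GEOM_CORONAL, noise_sigma=0.0, seed=1),
        AcquisitionSim(GEOM_AXIAL, noise_sigma=0.0, seed=2),
    )
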