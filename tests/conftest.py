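import numpy as np
import pytest

from ablamark.imaging_core import Mask
from ablamark.phantom import PhantomSpec, make_phantom_pair


@pytest.fixture(scope="session")
def small_phantom():
    """Desk-scale pre/post pair with ground truth (16x32x32 at 5x1x1 mm)."""
    spec = PhantomSpec(
        shape=(16, 32, 32),
        spacing=(5.0, 1.0, 1.0),
        tumor_radius_mm=5.0,
        ablation_radius_mm=8.0,
        n_vessel_landmarks=3,
        breathing_amplitude_mm=3.0,
        heating_amplitude_mm=1.0,
        noise_sd=0.01,
        seed=0,
    )
    return spec, make_phantom_pair(spec)


def sphere_mask(shape, spacing, center_mm, radius_mm):
    grids = np.meshgrid(*[np.arange(s) * sp for s, sp in zip(shape, spacing)], indexing="ij")
    pts = np.stack(grids, axis=-1)
    data = (np.sum((pts - np.asarray(center_mm)) ** 2, axis=-1) <= radius_mm**2).astype(np.uint8)
    return Mask(data, spacing)


@pytest.fixture
def make_sphere():
    return sphere_mask
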