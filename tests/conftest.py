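import numpy as np
import pytest

from peridose.cohort import BinaryMask, DoseGrid, ImageVolume


def digital_sphere(radius_mm: float, spacing: float = 1.0, margin_mm: float = 3.0) -> BinaryMask:
    """Voxelized sphere: voxels whose center lies within radius_mm of the center."""
    n = int(2 * (radius_mm + margin_mm) / spacing) + 1
    c = (n - 1) / 2.0
    x, y, z = np.mgrid[:n, :n, :n].astype(float)
    rho = spacing * np.sqrt((x - c) ** 2 + (y - c) ** 2 + (z - c) ** 2)
    return BinaryMask(rho <= radius_mm, (spacing,) * 3)


@pytest.fixture
def sphere_20mm() -> BinaryMask:
    return digital_sphere(20.0, spacing=1.0)


@pytest.fixture
def uniform_dose():
    def make(mask: BinaryMask, gy: float, n_fractions: int = 30) -> DoseGrid:
        return DoseGrid(np.full(mask.shape, float(gy)), n_fractions, mask.spacing)

    return make


@pytest.fixture
def random_volume():
    def make(shape=(8, 8, 8), seed=0, spacing=(1.0, 1.0, 1.0), lo=-1000, hi=1000,
             **kwargs) -> ImageVolume:
        rng = np.random.default_rng(seed)
        return ImageVolume(rng.integers(lo, hi + 1, size=shape).astype(float),
                           spacing, **kwargs)

    return make
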