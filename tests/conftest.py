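import numpy as np
import pytest

from spectrecon import (
    AcquisitionGeometry,
    AttenuationMap,
    GridSpec,
)


@pytest.fixture
def grid16():
    return GridSpec(16, 16, 1, pixel_size=1.0, slice_thickness=1.0)


@pytest.fixture
def geom8(grid16):
    """8 views over 360 deg, 16 bins aligned with the 16x16 grid."""
    return AcquisitionGeometry(
        n_bins=16, bin_width=1.0, angles=tuple(np.arange(8) * 45.0)
    )


@pytest.fixture
def water_disk_mu(grid16):
    """Uniform water disk of radius 6 cm centred in the 16x16 grid."""
    yy, xx = np.meshgrid(np.arange(16), np.arange(16), indexing="ij")
    disk = (xx - 7.5) ** 2 + (yy - 7.5) ** 2 <= 36
    return AttenuationMap(np.where(disk, 0.1538, 0.0), grid16)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_poisson_system(rng, n=24, m=8, scatter=False):
    """A small random emission system with Poisson data (helper, not a fixture)."""
    A = rng.uniform(0.1, 1.0, size=(n, m))
    beta = rng.uniform(0.0, 0.2, size=(n, m)) if scatter else np.zeros((n, m))
    f_true = rng.uniform(1.0, 10.0, size=m)
    g = rng.poisson(A @ f_true + beta @ f_true).astype(float)
    return A, beta, f_true, g
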