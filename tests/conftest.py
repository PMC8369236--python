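import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import braggshift as bs

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def water():
    return bs.WATER


@pytest.fixture(scope="session")
def coarse_grid():
    """Small phantom for fast dose-scoring tests (1 mm voxels)."""
    return bs.PhantomGrid(voxel=(0.1, 0.1, 0.1))


@pytest.fixture(scope="session")
def pencil_grid_100_b0(coarse_grid):
    return bs.simulate_dose_grid(
        bs.BeamSpec(100.0), bs.FieldSpec(0.0), coarse_grid, mode="pencil"
    )


def make_gaussian_slab(sigma_u, sigma_v, extent=8.0, pixel=0.05):
    """Analytic elliptical-Gaussian planar slab centred on the grid."""
    from braggshift.analysis import PlanarSlab

    n = int(round(extent / pixel))
    c = -extent / 2 + (np.arange(n) + 0.5) * pixel
    uu, vv = np.meshgrid(c, c, indexing="ij")
    vals = np.exp(-(uu**2 / (2 * sigma_u**2) + vv**2 / (2 * sigma_v**2)))
    vals /= vals.max()
    return PlanarSlab(values=vals, u=c, v=c, depth=0.0, pixel=(pixel, pixel))


@pytest.fixture(scope="session")
def gaussian_slab_builder():
    return make_gaussian_slab
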