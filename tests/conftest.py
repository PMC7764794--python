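import numpy as np
import pytest

from canopyqa import PointCloud


@pytest.fixture
def rng():
    return np.random.default_rng(20201210)


@pytest.fixture
def random_cloud(rng):
    """Factory for random clouds in a unit-ish box, optional channels."""

    def make(n=200, scale=1.0, with_rgb=False, with_nir=False, seed=None):
        r = np.random.default_rng(seed) if seed is not None else rng
        coords = r.uniform(-scale, scale, (n, 3))
        rgb = r.integers(0, 256, (n, 3)) if with_rgb else None
        nir = r.integers(0, 5000, n) if with_nir else None
        return PointCloud(coords=coords, rgb=rgb, nir=nir)

    return make
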