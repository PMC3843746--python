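import numpy as np
import pytest


def gaussian_plane(shape, amplitude, cy, cx, sy, sx, offset=0.0):
    """Sample a 2-D Gaussian + constant offset at pixel centers."""
    yy, xx = np.mgrid[: shape[0], : shape[1]].astype(float)
    return offset + amplitude * np.exp(
        -0.5 * (((yy - cy) / sy) ** 2 + ((xx - cx) / sx) ** 2)
    )


def gaussian_stack(shape, amplitude, cz, cy, cx, sz, sxy, offset=0.0):
    """Sample a 3-D Gaussian + constant offset at voxel centers."""
    zz, yy, xx = np.mgrid[: shape[0], : shape[1], : shape[2]].astype(float)
    return offset + amplitude * np.exp(
        -0.5 * (
            ((zz - cz) / sz) ** 2
            + ((yy - cy) / sxy) ** 2
            + ((xx - cx) / sxy) ** 2
        )
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
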