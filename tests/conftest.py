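import numpy as np
import pytest

from nodetex.volume_io import NormalizationParams, QuantizedROI


def make_quantized(levels_2d_or_3d, bits=4, mask=None):
    """Wrap an integer level array (levels in [1, 2**bits]) as a QuantizedROI."""
    levels = np.asarray(levels_2d_or_3d, dtype=np.int64)
    if levels.ndim == 2:
        levels = levels[:, :, None]
    if mask is None:
        mask = levels > 0
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.ndim == 2:
            mask = mask[:, :, None]
    out = np.zeros_like(levels)
    out[mask] = levels[mask]
    params = NormalizationParams(mu=0.0, sigma=1.0, bits=bits)
    return QuantizedROI(levels=out, mask=mask, params=params)


@pytest.fixture
def rng():
    return np.random.default_rng(20230126)


@pytest.fixture
def random_small_rois(rng):
    """Random 6x6x2 ROIs over 4 grey levels with random masks (for oracles)."""
    rois = []
    for _ in range(25):
        levels = rng.integers(1, 5, size=(6, 6, 2))
        mask = rng.random((6, 6, 2)) < 0.8
        mask[0, 0, 0] = True  # never empty
        rois.append(make_quantized(levels, bits=4, mask=mask))
    return rois
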