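import numpy as np
import pytest

from radbcr.imaging import (
    DiscretizationScheme,
    DiscretizedROI,
    ImageVolume,
    ROIMask,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_disc(levels: np.ndarray, n_levels: int | None = None,
              scheme: DiscretizationScheme | None = None) -> DiscretizedROI:
    """Wrap an integer level array (0 = background) as a DiscretizedROI."""
    levels = np.asarray(levels, dtype=np.int32)
    if levels.ndim == 2:
        levels = levels[..., None]
    g = int(n_levels if n_levels is not None else max(1, levels.max()))
    return DiscretizedROI(levels, g, scheme or DiscretizationScheme.fbn(max(2, g)))


def random_disc(rng: np.random.Generator, shape=(4, 4, 4), n_levels=4,
                roi_fraction=0.8) -> DiscretizedROI:
    """Random labeled ROI for oracle comparisons."""
    levels = rng.integers(1, n_levels + 1, size=shape).astype(np.int32)
    mask = rng.random(shape) < roi_fraction
    if not mask.any():
        mask.flat[0] = True
    levels[~mask] = 0
    return make_disc(levels, n_levels)


@pytest.fixture
def small_volume(rng):
    data = rng.normal(size=(5, 5, 5))
    vol = ImageVolume(data, (1.0, 1.0, 1.0), "test")
    mask = ROIMask(rng.random((5, 5, 5)) < 0.7)
    return vol, mask
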