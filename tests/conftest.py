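import numpy as np
import pytest

from spmkit import ImageSeries, ScanImage


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_image(rng, rows=16, cols=16, scale=50.0):
    z = rng.normal(0.0, scale, size=(rows, cols))
    return ScanImage(z, np.arange(cols, dtype=float), np.arange(rows, dtype=float))


@pytest.fixture
def small_image(rng):
    return random_image(rng)


@pytest.fixture
def flat_series(rng):
    """Five equal-shaped frames with distinct Z ranges, minimum rebased to 0."""
    frames = []
    for i in range(5):
        z = rng.uniform(0.0, 10.0 + 2.0 * i, size=(12, 12))
        z -= z.min()
        frames.append(ScanImage(z, np.arange(12, dtype=float),
                                np.arange(12, dtype=float),
                                {"filename": f"f{i}.txt"}))
    return ImageSeries(frames)
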