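import numpy as np
import pytest

from wbovw.imaging_io import GrayImage, RoiAnnotation
from wbovw.vocabulary import Vocabulary


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def ramp_image():
    """Horizontal ramp I(x, y) = x / (W - 1) on a 32x32 grid."""
    w = h = 32
    x = np.arange(w) / (w - 1)
    return GrayImage(np.tile(x, (h, 1)))


@pytest.fixture
def constant_image():
    return GrayImage(np.full((32, 32), 0.5))


@pytest.fixture
def center_annotation():
    return RoiAnnotation("img0", center_x=64, center_y=64, radius=40, label=0)


def make_vocabulary(K: int, dim: int, rng: np.random.Generator) -> Vocabulary:
    """A random but valid fitted-vocabulary object for encoder tests."""
    w = rng.uniform(0.5, 1.5, size=K)
    return Vocabulary(
        weights=w / w.sum(),
        means=rng.normal(size=(K, dim)),
        covariances=rng.uniform(0.5, 2.0, size=(K, dim)),
        loglik_trace=np.asarray([0.0]),
        seed=0,
    )


@pytest.fixture
def small_vocab(rng):
    return make_vocabulary(K=5, dim=6, rng=rng)
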