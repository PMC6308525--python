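import numpy as np
import pytest

from weedvision.synthetic import FieldSceneConfig, generate_histogram, generate_scene


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def bimodal_hist(rng):
    """A clean soil/vegetation mixture histogram (means 40/160, sd 12)."""
    return generate_histogram(veg_fraction=0.2, total=100_000, rng=rng)


@pytest.fixture
def scene():
    """A default three-row scene with two weedy inner gaps."""
    cfg = FieldSceneConfig(gap_fractions=(0.0, 0.05, 0.03, 0.0), seed=99)
    return generate_scene(cfg)


def two_delta(a: int, b: int, n_a: int = 50, n_b: int = 50) -> np.ndarray:
    """Histogram with all mass at two gray levels."""
    h = np.zeros(256, dtype=np.int64)
    h[a] = n_a
    h[b] = n_b
    return h
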