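import numpy as np
import pytest

from weedvision import between_class_variance, mean_gray, otsu_exhaustive, search_bounds
from weedvision.errors import DegenerateImageError, ValidationError
from weedvision.otsu import variance_curve

from conftest import two_delta


def naive_variance(counts, t):
    """Definitional two-pass between-class variance, independent of the cumsum path."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    lo, hi = counts[: t + 1], counts[t + 1 :]
    w0, w1 = lo.sum() / total, hi.sum() / total
    if w0 == 0 or w1 == 0:
        return 0.0
    mu0 = (np.arange(t + 1) * lo).sum() / lo.sum()
    mu1 = (np.arange(t + 1, counts.size) * hi).sum() / hi.sum()
    return w0 * w1 * (mu0 - mu1) ** 2


def naive_otsu(counts):
    """Brute-force double loop: best threshold, smallest on ties."""
    best_t, best_f = 0, -1.0
    for t in range(len(counts)):
        f = naive_variance(counts, t)
        if f > best_f:
            best_t, best_f = t, f
    return best_t, best_f


def test_mean_gray_examples():
    assert mean_gray(two_delta(42, 43, 100, 0)) == 42.0
    assert mean_gray(two_delta(0, 100, 1, 1)) == 50.0


def test_mean_gray_matches_per_pixel_mean(rng):
    h = rng.integers(0, 50, 256)
    pixels = np.repeat(np.arange(256), h)
    assert mean_gray(h) == pytest.approx(pixels.mean())


def test_search_bounds_two_delta_cases():
    b = search_bounds(two_delta(0, 100))
    assert (b.mu_l, b.mu_a, b.mu_b) == (50.0, 0.0, 100.0)
    b = search_bounds(two_delta(40, 160))
    assert (b.mu_a, b.mu_b) == (40.0, 160.0)


def test_search_bounds_bracket_otsu_threshold(bimodal_hist):
    b = search_bounds(bimodal_hist)
    t = otsu_exhaustive(bimodal_hist).threshold
    assert b.i_min <= b.mu_a <= b.mu_l <= b.mu_b <= b.i_max
    assert b.mu_a <= t <= b.mu_b


def test_variance_examples():
    assert between_class_variance(two_delta(0, 100), 50) == pytest.approx(2500.0)
    assert between_class_variance(two_delta(0, 100), 255) == 0.0


def test_variance_zero_at_degenerate_thresholds(rng):
    h = rng.integers(0, 30, 256)
    h[0] = h[255] = 5  # ensure occupied extremes
    curve = variance_curve(h)
    assert curve[255] == 0.0  # upper class empty


def test_variance_matches_two_pass_oracle(rng):
    h = rng.integers(0, 100, 256)
    curve = variance_curve(h)
    for t in range(0, 256, 7):
        assert curve[t] == pytest.approx(naive_variance(h, t), abs=1e-9)


def test_otsu_tie_breaks_to_smallest():
    # all t in [0, 99] tie at 2500; smallest wins
    res = otsu_exhaustive(two_delta(0, 100))
    assert res.threshold == 0
    assert res.fitness == pytest.approx(2500.0)
    assert res.evaluations == 256


def test_otsu_two_point_variance_value():
    res = otsu_exhaustive(two_delta(20, 200, 10, 10))
    assert res.fitness == pytest.approx(0.25 * 180**2)


def test_otsu_matches_brute_force_on_mixtures(rng):
    for _ in range(20):
        h = rng.integers(0, 200, 256)
        t_naive, _ = naive_otsu(h)
        assert otsu_exhaustive(h).threshold == t_naive


def test_otsu_shift_equivariance(rng):
    h = np.zeros(256, dtype=np.int64)
    h[10:90] = rng.integers(0, 500, 80)
    h[10] = h[89] = 50
    t0 = otsu_exhaustive(h).threshold
    for c in [1, 17, 100]:
        shifted = np.zeros(256, dtype=np.int64)
        shifted[c : c + 80] = h[10:90]
        assert otsu_exhaustive(shifted).threshold == t0 - 10 + c


def test_degenerate_single_level_rejected():
    with pytest.raises(DegenerateImageError):
        search_bounds(two_delta(42, 43, 100, 0))
    with pytest.raises(DegenerateImageError):
        otsu_exhaustive(two_delta(42, 43, 100, 0))
    with pytest.raises(ValidationError):
        mean_gray(np.zeros(256))
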