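import numpy as np
import pytest

from weedvision import (
    WeedMapper,
    classify_intensity,
    column_profile,
    extract_weed_map,
    find_interrow_intervals,
    weed_fractions,
)
from weedvision.errors import ValidationError
from weedvision.weedmap import LEVEL_NAMES, InterRowInterval


def profile_of(y):
    """Build a mask whose column profile equals y."""
    y = np.asarray(y)
    m = int(y.max()) + 1 if y.max() > 0 else 1
    mask = np.zeros((m, y.size), dtype=np.uint8)
    for j, c in enumerate(y):
        mask[:c, j] = 1
    return mask


def test_column_profile_single_column():
    mask = np.zeros((4, 4), dtype=np.uint8)
    mask[:, 1] = 1
    np.testing.assert_array_equal(column_profile(mask), [0, 4, 0, 0])


def test_column_profile_matches_per_pixel_tally(rng):
    mask = (rng.random((25, 40)) < 0.3).astype(np.uint8)
    expect = [int(mask[:, j].sum()) for j in range(40)]
    np.testing.assert_array_equal(column_profile(mask), expect)


def test_intervals_basic_valley():
    # cutoff = 10/3 = 3.33: columns 2,3 form one interval with 4 pixels
    iv = find_interrow_intervals(np.array([10, 10, 2, 2, 10]))
    assert iv == [InterRowInterval(2, 3, 4)]


def test_intervals_none_when_no_valley():
    assert find_interrow_intervals(np.array([10, 10, 10])) == []


def test_intervals_keep_border_runs():
    iv = find_interrow_intervals(np.array([0, 10, 0]))
    assert iv == [InterRowInterval(0, 0, 0), InterRowInterval(2, 2, 0)]


def test_intervals_empty_profile_flags_whole_image():
    iv = find_interrow_intervals(np.zeros(7, dtype=int))
    assert iv == [InterRowInterval(0, 6, 0)]


def test_interval_pixel_conservation(rng):
    """Interval sums plus non-interval column sums equal the mask total."""
    mask = (rng.random((30, 60)) < 0.25).astype(np.uint8)
    mask[:, 10] = 1  # a crop row to anchor max_y
    y = column_profile(mask)
    ivs = find_interrow_intervals(y)
    in_ivs = sum(iv.pixel_sum for iv in ivs)
    covered = np.zeros(60, dtype=bool)
    for iv in ivs:
        covered[iv.x1 : iv.x2 + 1] = True
    assert in_ivs + int(y[~covered].sum()) == int(mask.sum())


def test_weed_fraction_division():
    assert weed_fractions([InterRowInterval(0, 1, 4)], 50) == [pytest.approx(0.08)]
    assert weed_fractions([InterRowInterval(0, 1, 0)], 50) == [0.0]


def test_fraction_scale_invariance(rng):
    """Doubling image height at fixed column density leaves p(n) unchanged."""
    y = rng.integers(0, 10, 30)
    y[5] = 30
    mask1 = profile_of(y)
    mask2 = np.vstack([mask1, mask1])
    wm1 = extract_weed_map(mask1)
    wm2 = extract_weed_map(mask2)
    assert wm1.fractions == pytest.approx(wm2.fractions)


def test_intensity_levels_and_monotonicity():
    assert classify_intensity(0.0) == 0
    assert LEVEL_NAMES[classify_intensity(0.0)] == "no weeds"
    assert classify_intensity(1.0) == 5
    assert LEVEL_NAMES[5] == "very severe weeds"
    # default breakpoints (2, 5, 10, 15, 20)%: 19.42% falls in (15%, 20%]
    assert classify_intensity(0.1942) == 4
    assert classify_intensity(0.1306) == 3
    ps = np.linspace(0, 1, 101)
    levels = [classify_intensity(p) for p in ps]
    assert all(a <= b for a, b in zip(levels, levels[1:]))


def test_intensity_bad_breakpoints_rejected():
    with pytest.raises(ValidationError):
        classify_intensity(0.1, breakpoints=(0.05, 0.02, 0.1, 0.15, 0.2))


def test_adding_pixels_never_lowers_fraction_or_level(rng):
    y = np.array([20, 20, 1, 1, 1, 20, 20])
    mask = profile_of(y)
    wm = extract_weed_map(mask)
    denser = mask.copy()
    denser[5:10, 3] = 1  # more weeds inside the gap
    wm2 = extract_weed_map(denser)
    assert wm2.fractions[0] >= wm.fractions[0]
    assert wm2.levels[0] >= wm.levels[0]


def test_mapper_transpose_handles_horizontal_rows(scene):
    wm_v = WeedMapper().transform(scene.weed_mask | scene.crop_mask)
    wm_h = WeedMapper(transpose=True).transform((scene.weed_mask | scene.crop_mask).T)
    assert wm_v.fractions == pytest.approx(wm_h.fractions)


def test_weed_map_serialization_round_trip(scene):
    import json

    wm = extract_weed_map(scene.weed_mask | scene.crop_mask)
    d = json.loads(wm.to_json())
    assert d["fractions"] == pytest.approx(wm.fractions)
    assert len(d["intervals"]) == len(wm.intervals)
    frame = wm.to_frame()
    assert list(frame.columns) == ["x1", "x2", "pixel_sum", "fraction", "level", "label"]
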