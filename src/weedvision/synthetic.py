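"""Seeded synthetic field scenes with ground truth.

The generator emulates top-down grayscale images of a seedling row crop:
vertical crop rows over a soil background, with weeds clustered in the
inter-row gaps.  Vegetation is brighter than soil by default.  Every scene
carries its crop and weed masks and the true per-gap weed fractions, so the
segmentation and weed-mapping stages can be scored against ground truth
without field imagery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.draw import disk

from .errors import ValidationError
from .io import GRAY_LEVELS

#: Default gray statistics: dark soil, bright vegetation, moderate texture.
SOIL_MEAN, VEG_MEAN, GRAY_SD = 40.0, 160.0, 12.0


@dataclass
class FieldSceneConfig:
    """Parameters of a synthetic field scene.

    The image is ``height`` x ``width`` with ``n_rows`` vertical crop rows
    evenly spaced across the width.  Weed clusters are disks of radius
    ``weed_radius`` scattered in the inter-row gaps (including the border
    gaps) until each gap holds ``gap_fractions[i] * height * width`` weed
    pixels exactly.  Gray levels are Gaussian per class, plus an optional
    horizontal linear illumination gradient of peak-to-peak amplitude
    ``illumination`` and additive pixel noise of sd ``noise_sd``.
    """

    height: int = 240
    width: int = 320
    n_rows: int = 3
    row_half_width: int = 7
    row_jitter: int = 1
    soil_mean: float = SOIL_MEAN
    veg_mean: float = VEG_MEAN
    soil_sd: float = GRAY_SD
    veg_sd: float = GRAY_SD
    weed_radius: int = 4
    gap_fractions: tuple[float, ...] | float = 0.03
    illumination: float = 0.0
    noise_sd: float = 0.0
    seed: int | None = None

    def validate(self) -> None:
        if self.height < 8 or self.width < 8:
            raise ValidationError("scene must be at least 8x8 pixels")
        if self.n_rows < 1:
            raise ValidationError("need at least one crop row")
        if self.width // self.n_rows < 3 * (2 * self.row_half_width):
            raise ValidationError("rows too wide for the image: no inter-row gaps left")
        for m in (self.soil_mean, self.veg_mean):
            if not (0 <= m <= GRAY_LEVELS - 1):
                raise ValidationError("gray means must lie in [0, 255]")


@dataclass
class FieldScene:
    """A generated scene and its ground truth."""

    image: np.ndarray
    crop_mask: np.ndarray
    weed_mask: np.ndarray
    gap_bounds: list[tuple[int, int]]
    true_gap_fractions: list[float]
    config: FieldSceneConfig = field(repr=False, default=None)


def row_centers(cfg: FieldSceneConfig) -> list[int]:
    """Column centers of the crop rows, evenly spaced."""
    spacing = cfg.width / cfg.n_rows
    return [int(round((j + 0.5) * spacing)) for j in range(cfg.n_rows)]


def gap_column_ranges(cfg: FieldSceneConfig) -> list[tuple[int, int]]:
    """Inclusive column ranges of the inter-row gaps, borders included."""
    half = cfg.row_half_width + cfg.row_jitter
    edges: list[tuple[int, int]] = []
    prev = 0
    for c in row_centers(cfg):
        lo, hi = c - half, c + half
        if lo - 1 >= prev:
            edges.append((prev, lo - 1))
        prev = hi + 1
    if prev <= cfg.width - 1:
        edges.append((prev, cfg.width - 1))
    return edges


def max_gap_fractions(cfg: FieldSceneConfig) -> list[float]:
    """Largest weed fraction each gap can hold without over-filling columns.

    Weed columns are capped at 0.3 * height so that gap columns stay below
    the 1/3-of-maximum cutoff the weed mapper uses; the placement loop
    additionally refuses targets above 80% of that ceiling.
    """
    m, n = cfg.height, cfg.width
    col_cap = int(0.3 * m)
    return [0.8 * (hi - lo + 1) * col_cap / (m * n) for lo, hi in gap_column_ranges(cfg)]


def generate_scene(cfg: FieldSceneConfig, rng: np.random.Generator | None = None) -> FieldScene:
    """Generate one seeded field scene with ground-truth masks.

    Weed placement is exact: each gap receives precisely
    ``round(fraction * height * width)`` weed pixels, so
    ``true_gap_fractions`` equals the requested fractions up to rounding.
    Weed clusters are rejected when they would stack a single column higher
    than a quarter of the image — weed patches are low clumps, not
    row-spanning strips — which keeps the column-profile valley structure
    of a real inter-row gap.
    """
    cfg.validate()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    m, n = cfg.height, cfg.width
    shape = (m, n)

    crop = np.zeros(shape, dtype=np.uint8)
    for c in row_centers(cfg):
        step = max(cfg.row_half_width // 2, 1)
        for r in range(0, m, step):
            jc = c + int(rng.integers(-cfg.row_jitter, cfg.row_jitter + 1))
            rr, cc = disk((r, jc), cfg.row_half_width, shape=shape)
            crop[rr, cc] = 1

    gaps = gap_column_ranges(cfg)
    fracs = cfg.gap_fractions
    if np.isscalar(fracs):
        fracs = tuple(float(fracs) for _ in gaps)
    if len(fracs) != len(gaps):
        raise ValidationError(f"{len(gaps)} gaps but {len(fracs)} gap_fractions")

    weed = np.zeros(shape, dtype=np.uint8)
    true_fracs: list[float] = []
    col_cap = int(0.3 * m)  # keep weed columns below the 1/3 gap cutoff of crop-row height
    for (lo, hi), frac in zip(gaps, fracs):
        if not (0 <= frac < 1):
            raise ValidationError("gap fractions must lie in [0, 1)")
        target = int(round(frac * m * n))
        usable_lo = lo + cfg.weed_radius
        usable_hi = hi - cfg.weed_radius
        if usable_hi < usable_lo:
            if target > 0:
                raise ValidationError("gap too narrow for the requested weed fraction")
            true_fracs.append(0.0)
            continue
        capacity = (hi - lo + 1) * col_cap
        if target > 0.8 * capacity:
            raise ValidationError(
                f"weed fraction {frac} infeasible for gap [{lo}, {hi}] "
                f"(target {target} px, capacity ~{capacity} px)"
            )
        _fill_gap(weed, target, usable_lo, usable_hi, cfg.weed_radius, col_cap, rng)
        true_fracs.append(weed[:, lo : hi + 1].sum() / (m * n))

    soil_px = rng.normal(cfg.soil_mean, cfg.soil_sd, shape)
    veg_px = rng.normal(cfg.veg_mean, cfg.veg_sd, shape)
    veg = (crop | weed).astype(bool)
    img = np.where(veg, veg_px, soil_px)
    if cfg.illumination:
        img += cfg.illumination * (np.arange(n) / max(n - 1, 1) - 0.5)
    if cfg.noise_sd:
        img += rng.normal(0.0, cfg.noise_sd, shape)
    image = np.clip(np.rint(img), 0, GRAY_LEVELS - 1).astype(np.uint8)

    return FieldScene(
        image=image,
        crop_mask=crop,
        weed_mask=weed,
        gap_bounds=gaps,
        true_gap_fractions=true_fracs,
        config=cfg,
    )


def _fill_gap(
    weed: np.ndarray,
    target: int,
    col_lo: int,
    col_hi: int,
    radius: int,
    col_cap: int,
    rng: np.random.Generator,
) -> None:
    """Scatter weed disks in [col_lo, col_hi] until exactly ``target`` pixels are set."""
    m = weed.shape[0]
    count = 0
    while count < target:
        placed = False
        for _ in range(200):  # rejection loop against over-tall columns
            r = int(rng.integers(0, m))
            c = int(rng.integers(col_lo, col_hi + 1))
            rr, cc = disk((r, c), radius, shape=weed.shape)
            new = rr[weed[rr, cc] == 0], cc[weed[rr, cc] == 0]
            if new[0].size == 0:
                continue
            trial_counts = np.bincount(new[1], minlength=weed.shape[1])
            cols = np.unique(new[1])
            if np.any(weed[:, cols].sum(axis=0) + trial_counts[cols] > col_cap):
                continue
            placed = True
            break
        if not placed:
            raise ValidationError("could not place weed clusters without over-filling columns")
        excess = count + new[0].size - target
        if excess > 0:  # trim the last disk so the pixel count is exact
            keep = rng.permutation(new[0].size)[: new[0].size - excess]
            new = new[0][keep], new[1][keep]
        weed[new] = 1
        count += new[0].size


def generate_histogram(
    soil_mean: float = SOIL_MEAN,
    veg_mean: float = VEG_MEAN,
    soil_sd: float = GRAY_SD,
    veg_sd: float = GRAY_SD,
    veg_fraction: float = 0.2,
    total: int = 100_000,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Two-component Gaussian-mixture gray histogram with an exact pixel total.

    A fast stand-in for a full scene when only the histogram matters (e.g.
    optimizer benchmarks): ``round(veg_fraction * total)`` vegetation pixels
    and the remainder soil pixels, each Gaussian around its class mean,
    rounded and clipped to [0, 255].
    """
    if not (0 < veg_fraction < 1):
        raise ValidationError("veg_fraction must lie strictly in (0, 1)")
    for mu in (soil_mean, veg_mean):
        if not (0 <= mu <= GRAY_LEVELS - 1):
            raise ValidationError("means must lie in [0, 255]")
    rng = rng if rng is not None else np.random.default_rng()
    n_veg = int(round(veg_fraction * total))
    soil = rng.normal(soil_mean, soil_sd, total - n_veg)
    veg = rng.normal(veg_mean, veg_sd, n_veg)
    px = np.clip(np.rint(np.concatenate([soil, veg])), 0, GRAY_LEVELS - 1).astype(np.int64)
    return np.bincount(px, minlength=GRAY_LEVELS).astype(np.int64)
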