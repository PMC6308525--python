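"""Inter-row weed distribution maps from binary vegetation masks.

Crop rows stand as tall peaks in the lateral (per-column) histogram of a
binary mask; the valleys between them are the inter-row gaps where any
vegetation is weed.  An inter-row interval is a maximal run of columns
whose foreground count stays at or below ``fraction * max(y)`` (default
1/3).  Each interval's weed pixel sum, divided by the total image size,
gives the weed fraction p(n), which a six-level intensity scale turns
into a spray decision input.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import ValidationError
from .io import _check_mask

#: Six weed-intensity labels, level 0 .. 5.
LEVEL_NAMES = (
    "no weeds",
    "few weeds",
    "moderate weeds",
    "many weeds",
    "severe weeds",
    "very severe weeds",
)

#: Default level breakpoints as fractions of total image pixels.
DEFAULT_BREAKPOINTS = (0.02, 0.05, 0.10, 0.15, 0.20)


@dataclass(frozen=True)
class InterRowInterval:
    """A maximal low-count column run [x1, x2] and its foreground pixel sum."""

    x1: int
    x2: int
    pixel_sum: int

    @property
    def width(self) -> int:
        return self.x2 - self.x1 + 1


@dataclass
class WeedMap:
    """Per-interval weed fractions and intensity levels for one image."""

    intervals: list[InterRowInterval]
    fractions: list[float]
    levels: list[int]
    image_shape: tuple[int, int]
    no_vegetation: bool = False
    level_names: tuple[str, ...] = field(default=LEVEL_NAMES, repr=False)

    def to_json(self) -> str:
        d = asdict(self)
        d["level_names"] = list(self.level_names)
        return json.dumps(d)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x1": [iv.x1 for iv in self.intervals],
                "x2": [iv.x2 for iv in self.intervals],
                "pixel_sum": [iv.pixel_sum for iv in self.intervals],
                "fraction": self.fractions,
                "level": self.levels,
                "label": [self.level_names[lv] for lv in self.levels],
            }
        )


def column_profile(mask: np.ndarray) -> np.ndarray:
    """Lateral histogram: y[j] = number of 1-pixels in column j."""
    mask = _check_mask(mask)
    return mask.sum(axis=0).astype(np.int64)


def find_interrow_intervals(
    profile: np.ndarray, fraction: float = 1.0 / 3.0
) -> list[InterRowInterval]:
    """Maximal runs of columns with y <= fraction * max(y).

    Runs touching the image borders are kept: an edge gap is as real a
    spray target as an interior one.  A profile with no vegetation at all
    (max(y) == 0) returns the whole image as a single interval; callers
    should treat that as "no vegetation" rather than "one huge gap".
    """
    y = np.asarray(profile)
    if y.ndim != 1 or y.size == 0:
        raise ValidationError("profile must be a non-empty 1-D array")
    if not (0 < fraction < 1):
        raise ValidationError("fraction must lie strictly in (0, 1)")
    max_y = int(y.max())
    if max_y == 0:
        return [InterRowInterval(0, y.size - 1, 0)]
    low = y <= fraction * max_y
    intervals: list[InterRowInterval] = []
    j = 0
    while j < y.size:
        if low[j]:
            k = j
            while k + 1 < y.size and low[k + 1]:
                k += 1
            intervals.append(InterRowInterval(j, k, int(y[j : k + 1].sum())))
            j = k + 1
        else:
            j += 1
    return intervals


def weed_fractions(intervals: list[InterRowInterval], image_total: int) -> list[float]:
    """p(n) = interval pixel sum / total image pixels, per interval."""
    if image_total <= 0:
        raise ValidationError("image_total must be positive")
    return [iv.pixel_sum / image_total for iv in intervals]


def classify_intensity(
    p: float, breakpoints: tuple[float, ...] = DEFAULT_BREAKPOINTS
) -> int:
    """Weed-intensity level 0..5: the number of breakpoints strictly below p.

    With the default breakpoints (2, 5, 10, 15, 20)% of image pixels the
    levels are [0, 2%], (2, 5%], ..., (20%, 1].  p = 0 is always level 0
    ("no weeds") and the level is monotone in p.
    """
    bp = np.asarray(breakpoints, dtype=float)
    if bp.size != 5 or (np.diff(bp) <= 0).any() or bp[0] <= 0 or bp[-1] >= 1:
        raise ValidationError("breakpoints must be 5 strictly ascending fractions in (0, 1)")
    if not (0 <= p <= 1):
        raise ValidationError("p must lie in [0, 1]")
    return int((p > bp).sum())


class WeedMapper(TransformerMixin, BaseEstimator):
    """Extract a :class:`WeedMap` from a binary vegetation mask.

    Parameters
    ----------
    fraction : float, default 1/3
        Cut fraction of the lateral-histogram maximum below which a column
        belongs to an inter-row gap.
    breakpoints : tuple of 5 floats
        Ascending weed-fraction breakpoints separating the six intensity
        levels.
    transpose : bool, default False
        Set when crop rows run horizontally in the image; the mask is
        transposed before profiling.
    """

    def __init__(
        self,
        fraction: float = 1.0 / 3.0,
        breakpoints: tuple[float, ...] = DEFAULT_BREAKPOINTS,
        transpose: bool = False,
    ):
        self.fraction = fraction
        self.breakpoints = breakpoints
        self.transpose = transpose

    def fit(self, X: np.ndarray, y=None) -> "WeedMapper":
        mask = _check_mask(np.asarray(X).T if self.transpose else np.asarray(X))
        self.profile_ = column_profile(mask)
        no_veg = int(self.profile_.max()) == 0
        self.intervals_ = find_interrow_intervals(self.profile_, self.fraction)
        fracs = weed_fractions(self.intervals_, mask.size)
        levels = [classify_intensity(p, self.breakpoints) for p in fracs]
        self.weed_map_ = WeedMap(
            intervals=self.intervals_,
            fractions=fracs,
            levels=levels,
            image_shape=mask.shape,
            no_vegetation=no_veg,
        )
        return self

    def transform(self, X: np.ndarray) -> WeedMap:
        """Fit on the mask and return its weed map."""
        return self.fit(X).weed_map_


def extract_weed_map(
    mask: np.ndarray,
    fraction: float = 1.0 / 3.0,
    breakpoints: tuple[float, ...] = DEFAULT_BREAKPOINTS,
    transpose: bool = False,
) -> WeedMap:
    """One-call wrapper around :class:`WeedMapper`."""
    return WeedMapper(fraction=fraction, breakpoints=breakpoints, transpose=transpose).transform(
        mask
    )


def render_profile(profile: np.ndarray, path: str, fraction: float = 1.0 / 3.0) -> None:
    """Save a lateral-histogram plot with the gap cutoff line (needs matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 3))
    ax.bar(np.arange(profile.size), profile, width=1.0, color="forestgreen")
    ax.axhline(fraction * profile.max(), color="crimson", ls="--", label=f"{fraction:.2f} x max(y)")
    ax.set_xlabel("image column")
    ax.set_ylabel("foreground pixels")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
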