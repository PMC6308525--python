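"""Otsu between-class-variance threshold selection on gray-level histograms.

All routines operate on a 256-bin histogram ``counts`` where ``counts[i]`` is
the number of pixels of gray level ``i``.  The two classes induced by a
threshold ``t`` are {gray <= t} (background side) and {gray > t}; this
inclusive/strict split is used consistently everywhere in the package.
Ties in variance are always broken toward the smallest threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateImageError, ValidationError


@dataclass(frozen=True)
class SearchBounds:
    """Contracted search range for swarm threshold search.

    ``mu_l`` is the global mean gray; the histogram is split at ``mu_l`` into
    a low region A = [i_min, floor(mu_l)] and a high region
    B = [ceil(mu_l), i_max], and ``mu_a``/``mu_b`` are the gray-weighted means
    of those regions.  For a bimodal vegetation/soil histogram [mu_a, mu_b]
    brackets the optimal threshold in a range much narrower than
    [i_min, i_max].
    """

    mu_l: float
    i_min: int
    i_max: int
    mu_a: float
    mu_b: float


def _check_hist(counts: np.ndarray) -> np.ndarray:
    counts = np.asarray(counts, dtype=np.float64)
    if counts.ndim != 1 or counts.size < 2:
        raise ValidationError("histogram must be a 1-D array of >= 2 bins")
    if (counts < 0).any():
        raise ValidationError("histogram counts must be non-negative")
    if counts.sum() <= 0:
        raise ValidationError("empty histogram")
    return counts


def mean_gray(counts: np.ndarray) -> float:
    """Mean gray level of the image: sum(i * n_i) / (M*N)."""
    counts = _check_hist(counts)
    levels = np.arange(counts.size)
    return float((levels * counts).sum() / counts.sum())


def occupied_range(counts: np.ndarray) -> tuple[int, int]:
    """Lowest and highest gray levels with a nonzero count."""
    counts = _check_hist(counts)
    nz = np.flatnonzero(counts)
    if nz.size < 2:
        raise DegenerateImageError("fewer than two occupied gray levels")
    return int(nz[0]), int(nz[-1])


def search_bounds(counts: np.ndarray) -> SearchBounds:
    """Compute the contracted swarm search range [mu_a, mu_b].

    The image mean mu_l splits the occupied range into a low and a high
    region, whose gray-weighted means mu_a and mu_b become the search bounds.
    The split bins are [i_min, floor(mu_l)] and [ceil(mu_l), i_max]; when
    mu_l is an integer that bin belongs to both regions.
    """
    counts = _check_hist(counts)
    i_min, i_max = occupied_range(counts)
    mu_l = mean_gray(counts)
    levels = np.arange(counts.size)

    lo_hi = int(np.floor(mu_l))
    hi_lo = int(np.ceil(mu_l))
    a = slice(i_min, lo_hi + 1)
    b = slice(hi_lo, i_max + 1)
    mass_a = counts[a].sum()
    mass_b = counts[b].sum()
    # i_min and i_max are occupied and mu_l lies strictly between them,
    # so both regions hold pixels.
    mu_a = float((levels[a] * counts[a]).sum() / mass_a)
    mu_b = float((levels[b] * counts[b]).sum() / mass_b)
    return SearchBounds(mu_l=mu_l, i_min=i_min, i_max=i_max, mu_a=mu_a, mu_b=mu_b)


def variance_curve(counts: np.ndarray) -> np.ndarray:
    """Between-class variance at every threshold t = 0 .. L-1.

    sigma^2(t) = w0(t) * w1(t) * (mu0(t) - mu1(t))^2 with w the class
    probability masses and mu the class mean grays of {<=t} / {>t};
    0 where a class is empty.  Computed with cumulative sums, one pass.
    """
    counts = _check_hist(counts)
    total = counts.sum()
    levels = np.arange(counts.size)
    # cumulate raw counts before normalizing: for integer counts the partial
    # sums are exact, so w1 is exactly 0 at the top threshold
    cum = np.cumsum(counts)
    w0 = cum / total
    m0 = np.cumsum(counts * levels) / total
    mt = m0[-1]
    w1 = (total - cum) / total
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = np.where(w0 > 0, m0 / w0, 0.0)
        mu1 = np.where(w1 > 0, (mt - m0) / w1, 0.0)
    sigma2 = w0 * w1 * (mu0 - mu1) ** 2
    sigma2[(w0 == 0) | (w1 == 0)] = 0.0
    return sigma2


def between_class_variance(counts: np.ndarray, t: int) -> float:
    """Between-class variance of the split {<=t} / {>t}."""
    counts = _check_hist(counts)
    if not (0 <= int(t) < counts.size):
        raise ValidationError(f"threshold {t} outside [0, {counts.size - 1}]")
    return float(variance_curve(counts)[int(t)])


def best_threshold(sigma2: np.ndarray) -> int:
    """Argmax of a variance curve, smallest threshold on ties."""
    return int(np.argmax(sigma2))  # np.argmax returns the first maximum
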