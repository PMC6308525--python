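"""Grayscale image and binary-mask I/O, histograms, and thresholding.

Images are plain ``uint8`` numpy arrays of shape (M, N) with gray levels in
[0, L-1], L = 256.  Binary masks are {0, 1} arrays of the same shape; on disk
they are stored as 8-bit PNGs with values {0, 255}.
"""

from __future__ import annotations

import logging
import os

import imageio.v3 as iio
import numpy as np

from .errors import ValidationError

logger = logging.getLogger(__name__)

#: Number of gray levels in an 8-bit image.
GRAY_LEVELS = 256


def read_gray_image(path: str | os.PathLike) -> np.ndarray:
    """Read an image as an 8-bit grayscale array.

    Multi-channel images are converted by averaging the channels (an alpha
    channel, if present, is dropped first); a warning is logged because the
    conversion discards color information.

    Parameters
    ----------
    path : path-like
        PNG, TIFF or BMP file.

    Returns
    -------
    ndarray of uint8, shape (M, N)
    """
    arr = iio.imread(path)
    if arr.ndim == 3:
        if arr.shape[2] == 4:  # RGBA: drop alpha
            arr = arr[:, :, :3]
        logger.warning("multi-channel image %s converted to gray by channel average", path)
        arr = arr.astype(np.float64).mean(axis=2)
        arr = np.rint(arr)
    if arr.ndim != 2:
        raise ValidationError(f"expected a 2-D image, got shape {arr.shape}")
    if arr.size == 0:
        raise ValidationError("zero-size image")
    return np.clip(arr, 0, GRAY_LEVELS - 1).astype(np.uint8)


def write_gray_image(path: str | os.PathLike, image: np.ndarray) -> None:
    """Write a grayscale image as an 8-bit file (format from extension)."""
    image = _check_image(image)
    iio.imwrite(path, image)


def read_mask(path: str | os.PathLike) -> np.ndarray:
    """Read a binary mask stored as an 8-bit image; any nonzero pixel is 1."""
    arr = read_gray_image(path)
    return (arr > 0).astype(np.uint8)


def write_mask(path: str | os.PathLike, mask: np.ndarray) -> None:
    """Write a {0,1} mask as an 8-bit image with values {0, 255}."""
    mask = _check_mask(mask)
    iio.imwrite(path, (mask * 255).astype(np.uint8))


def compute_histogram(image: np.ndarray) -> np.ndarray:
    """256-bin gray-level histogram: counts[i] = number of pixels of gray i.

    The counts always sum to M*N.
    """
    image = _check_image(image)
    return np.bincount(image.ravel(), minlength=GRAY_LEVELS).astype(np.int64)


def apply_threshold(image: np.ndarray, t: int, foreground: str = "above") -> np.ndarray:
    """Binarize an image at threshold ``t``.

    The two classes are gray <= t and gray > t.  With ``foreground="above"``
    (the default: vegetation brighter than soil) pixels strictly above ``t``
    become 1; with ``"below"`` pixels <= t become 1.  The two polarities
    produce complementary masks.
    """
    image = _check_image(image)
    if not (0 <= int(t) <= GRAY_LEVELS - 1):
        raise ValidationError(f"threshold {t} outside [0, {GRAY_LEVELS - 1}]")
    if foreground == "above":
        return (image > t).astype(np.uint8)
    if foreground == "below":
        return (image <= t).astype(np.uint8)
    raise ValidationError(f"foreground must be 'above' or 'below', got {foreground!r}")


def _check_image(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 2 or image.size == 0:
        raise ValidationError(f"expected a non-empty 2-D image, got shape {image.shape}")
    if image.dtype != np.uint8:
        if image.min() < 0 or image.max() > GRAY_LEVELS - 1:
            raise ValidationError("pixel values outside [0, 255]")
        image = image.astype(np.uint8)
    return image


def _check_mask(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.ndim != 2 or mask.size == 0:
        raise ValidationError(f"expected a non-empty 2-D mask, got shape {mask.shape}")
    vals = np.unique(mask)
    if not np.isin(vals, [0, 1]).all():
        raise ValidationError("mask must contain only 0/1 values")
    return mask.astype(np.uint8)
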