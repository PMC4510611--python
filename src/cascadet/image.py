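"""Grayscale image handling and summed-area tables.

Images are plain 2-D numpy arrays of non-negative, finite intensities
(float or integer). The integral image (summed-area table) lets any
axis-aligned rectangle be summed with four lookups, which is the substrate
for fast Haar-like feature evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import imageio.v3 as iio

# ITU-R BT.601 luma weights, used when a colour raster is loaded.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)


@dataclass(frozen=True)
class Rect:
    """Axis-aligned pixel rectangle: top-left corner (y, x), size (h, w).

    Coordinates are 0-based and row-major; the rectangle covers pixel rows
    ``y .. y+h-1`` and columns ``x .. x+w-1`` inclusive.
    """

    y: int
    x: int
    h: int
    w: int

    def __post_init__(self) -> None:
        if self.h < 1 or self.w < 1:
            raise ValueError(f"rectangle must have h >= 1 and w >= 1, got {self}")
        if self.y < 0 or self.x < 0:
            raise ValueError(f"rectangle origin must be non-negative, got {self}")

    @property
    def area(self) -> int:
        return self.h * self.w

    def inside(self, height: int, width: int) -> bool:
        return self.y + self.h <= height and self.x + self.w <= width


def as_gray_image(img: np.ndarray) -> np.ndarray:
    """Validate and return a 2-D grayscale array.

    Raises ``ValueError`` for empty, non-2-D, negative or non-finite input.
    """
    arr = np.asarray(img)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError(f"expected a non-empty 2-D image, got shape {arr.shape}")
    if not np.all(np.isfinite(arr.astype(np.float64))):
        raise ValueError("image contains non-finite intensities")
    if np.any(arr < 0):
        raise ValueError("image contains negative intensities")
    return arr


def integral_image(img: np.ndarray) -> np.ndarray:
    """Summed-area table with a zero padding row/column.

    Entry ``(y, x)`` of the returned ``(H+1, W+1)`` array holds the sum of
    all pixels strictly above and left of ``(y, x)``, so that any rectangle
    sum needs four lookups. Integer input stays in exact int64 arithmetic.
    """
    arr = as_gray_image(img)
    dtype = np.int64 if np.issubdtype(arr.dtype, np.integer) else np.float64
    out = np.zeros((arr.shape[0] + 1, arr.shape[1] + 1), dtype=dtype)
    np.cumsum(np.cumsum(arr, axis=0, dtype=dtype), axis=1, out=out[1:, 1:])
    return out


def rect_sum(ii: np.ndarray, r: Rect) -> float:
    """Sum of pixel intensities inside ``r`` from an integral image."""
    height, width = ii.shape[0] - 1, ii.shape[1] - 1
    if not r.inside(height, width):
        raise ValueError(f"rectangle {r} outside {height}x{width} image")
    y0, x0, y1, x1 = r.y, r.x, r.y + r.h, r.x + r.w
    return ii[y1, x1] - ii[y0, x1] - ii[y1, x0] + ii[y0, x0]


def load_gray(path) -> np.ndarray:
    """Read a lossless raster (PNG/PGM); colour is converted with BT.601 luma."""
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., :3].astype(np.float64) @ np.asarray(LUMA_WEIGHTS)
    return as_gray_image(np.asarray(arr, dtype=np.float64))


def save_gray(path, img: np.ndarray) -> None:
    """Write a grayscale array as an 8-bit raster, clipping to [0, 255]."""
    arr = np.clip(np.asarray(img, dtype=np.float64), 0, 255)
    iio.imwrite(path, np.round(arr).astype(np.uint8))
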