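"""Rectangular Haar-like features evaluated through integral images.

Five prototypes are supported, the classic 2-, 3- and 4-rectangle kinds:

* ``TWO_H`` — two horizontally adjacent rectangles, left minus right;
* ``TWO_V`` — two vertically adjacent rectangles, top minus bottom;
* ``THREE_H`` / ``THREE_V`` — three adjacent rectangles, centre minus the
  two outer ones;
* ``FOUR`` — 2x2 block of rectangles, main-diagonal pair minus
  anti-diagonal pair.

Each feature is the difference of pixel sums over its rectangles; with an
integral image every evaluation costs a handful of lookups regardless of
scale. Sign conventions are fixed but arbitrary: a boosted stump absorbs
any consistent sign through its polarity.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

from .image import Rect, as_gray_image, integral_image, rect_sum


class HaarKind(str, Enum):
    TWO_H = "TWO_H"
    TWO_V = "TWO_V"
    THREE_H = "THREE_H"
    THREE_V = "THREE_V"
    FOUR = "FOUR"


#: (height divisor, width divisor) of each prototype's footprint
_DIVISORS = {
    HaarKind.TWO_H: (1, 2),
    HaarKind.TWO_V: (2, 1),
    HaarKind.THREE_H: (1, 3),
    HaarKind.THREE_V: (3, 1),
    HaarKind.FOUR: (2, 2),
}

_KIND_ORDER = [HaarKind.TWO_H, HaarKind.TWO_V, HaarKind.THREE_H,
               HaarKind.THREE_V, HaarKind.FOUR]


@dataclass(frozen=True)
class HaarFeature:
    """One Haar-like feature: a prototype kind and its footprint rectangle."""

    kind: HaarKind
    base_rect: Rect

    def __post_init__(self) -> None:
        dh, dw = _DIVISORS[HaarKind(self.kind)]
        r = self.base_rect
        if r.h % dh or r.w % dw:
            raise ValueError(
                f"{self.kind} footprint {r.h}x{r.w} not divisible by ({dh}, {dw})"
            )


def signed_rects(f: HaarFeature) -> list[tuple[int, Rect]]:
    """Decompose a feature into ``(sign, rectangle)`` terms.

    The feature value is ``sum(sign * pixel_sum(rect))``.
    """
    r = f.base_rect
    kind = HaarKind(f.kind)
    if kind is HaarKind.TWO_H:
        hw = r.w // 2
        return [(+1, Rect(r.y, r.x, r.h, hw)), (-1, Rect(r.y, r.x + hw, r.h, hw))]
    if kind is HaarKind.TWO_V:
        hh = r.h // 2
        return [(+1, Rect(r.y, r.x, hh, r.w)), (-1, Rect(r.y + hh, r.x, hh, r.w))]
    if kind is HaarKind.THREE_H:
        tw = r.w // 3
        return [
            (-1, Rect(r.y, r.x, r.h, tw)),
            (+1, Rect(r.y, r.x + tw, r.h, tw)),
            (-1, Rect(r.y, r.x + 2 * tw, r.h, tw)),
        ]
    if kind is HaarKind.THREE_V:
        th = r.h // 3
        return [
            (-1, Rect(r.y, r.x, th, r.w)),
            (+1, Rect(r.y + th, r.x, th, r.w)),
            (-1, Rect(r.y + 2 * th, r.x, th, r.w)),
        ]
    # FOUR: (top-left + bottom-right) - (top-right + bottom-left)
    hh, hw = r.h // 2, r.w // 2
    return [
        (+1, Rect(r.y, r.x, hh, hw)),
        (-1, Rect(r.y, r.x + hw, hh, hw)),
        (-1, Rect(r.y + hh, r.x, hh, hw)),
        (+1, Rect(r.y + hh, r.x + hw, hh, hw)),
    ]


def eval_haar(ii: np.ndarray, f: HaarFeature) -> float:
    """Evaluate one feature on a precomputed integral image."""
    return sum(s * rect_sum(ii, r) for s, r in signed_rects(f))


def enumerate_haar(
    window_h: int,
    window_w: int,
    stride: int = 1,
    scale_step: int = 1,
) -> list[HaarFeature]:
    """Enumerate all admissible features on a ``window_h x window_w`` window.

    ``stride`` thins feature positions, ``scale_step`` thins footprint
    scales (both default to the exhaustive setting 1). The result is a
    deterministic, duplicate-free list: kinds in a fixed order, then
    footprint height, width, y, x ascending.
    """
    if window_h < 1 or window_w < 1:
        raise ValueError("window dimensions must be >= 1")
    if stride < 1 or scale_step < 1:
        raise ValueError("stride and scale_step must be >= 1")
    feats: list[HaarFeature] = []
    for kind in _KIND_ORDER:
        dh, dw = _DIVISORS[kind]
        for mh in range(1, window_h // dh + 1, scale_step):
            h = mh * dh
            for mw in range(1, window_w // dw + 1, scale_step):
                w = mw * dw
                for y in range(0, window_h - h + 1, stride):
                    for x in range(0, window_w - w + 1, stride):
                        feats.append(HaarFeature(kind, Rect(y, x, h, w)))
    return feats


def extract_haar_vector(
    img: np.ndarray, features: Sequence[HaarFeature], window: tuple[int, int] | None = None
) -> np.ndarray:
    """Feature vector of ``eval_haar`` values in enumeration order."""
    arr = as_gray_image(img)
    if window is not None and arr.shape != tuple(window):
        raise ValueError(f"image shape {arr.shape} does not match window {window}")
    ii = integral_image(arr)
    return np.array([eval_haar(ii, f) for f in features], dtype=np.float64)


def _corner_tables(features: Sequence[HaarFeature]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Flattened (weight, y, x) integral-image lookup tables per feature.

    Each rectangle contributes its four summed-area corners; a feature of
    ``k`` rectangles becomes ``4k`` weighted lookups.
    """
    wts, ys, xs = [], [], []
    for f in features:
        fw, fy, fx = [], [], []
        for s, r in signed_rects(f):
            y0, x0, y1, x1 = r.y, r.x, r.y + r.h, r.x + r.w
            fw += [s, s, -s, -s]
            fy += [y1, y0, y0, y1]
            fx += [x1, x0, x1, x0]
        wts.append(fw)
        ys.append(fy)
        xs.append(fx)
    width = max(len(v) for v in wts)
    n = len(features)
    w_arr = np.zeros((n, width))
    y_arr = np.zeros((n, width), dtype=np.intp)
    x_arr = np.zeros((n, width), dtype=np.intp)
    for i, (fw, fy, fx) in enumerate(zip(wts, ys, xs)):
        w_arr[i, : len(fw)] = fw
        y_arr[i, : len(fy)] = fy
        x_arr[i, : len(fx)] = fx
    return w_arr, y_arr, x_arr


def extract_haar_matrix(imgs: Iterable[np.ndarray], features: Sequence[HaarFeature]) -> np.ndarray:
    """Feature matrix (n_images x n_features), vectorised over images.

    All images must share one shape (the enumeration window).
    """
    stack = np.stack([as_gray_image(im).astype(np.float64) for im in imgs])
    iis = np.pad(stack.cumsum(axis=1).cumsum(axis=2), ((0, 0), (1, 0), (1, 0)))
    w_arr, y_arr, x_arr = _corner_tables(features)
    out = np.empty((stack.shape[0], len(features)))
    for j in range(len(features)):
        out[:, j] = iis[:, y_arr[j], x_arr[j]] @ w_arr[j]
    return out
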