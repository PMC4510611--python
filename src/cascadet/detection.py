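"""Whole-image detection by multi-scale sliding window.

The image is repeatedly downscaled by ``scale_factor`` (an image pyramid)
and a fixed-size window slides over each level in raster order; window
contents are evaluated at the cascade's native window size and accepted
windows are mapped back to original-image coordinates. Overlapping
detections are optionally merged by greedy non-maximum suppression.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
from skimage.transform import resize

from .cascade import CascadeModel
from .features import Extractor, build_extractor
from .image import Rect, as_gray_image


@dataclass(frozen=True)
class Detection:
    """One accepted window in original-image coordinates."""

    rect: Rect
    score: float  # exit margin at the final stage
    scale: float


def iou(a: Rect, b: Rect) -> float:
    """Intersection-over-union of two rectangles."""
    y0, x0 = max(a.y, b.y), max(a.x, b.x)
    y1, x1 = min(a.y + a.h, b.y + b.h), min(a.x + a.w, b.x + b.w)
    inter = max(0, y1 - y0) * max(0, x1 - x0)
    return inter / (a.area + b.area - inter) if inter else 0.0


def pyramid_scales(
    img_h: int,
    img_w: int,
    window_h: int,
    window_w: int,
    scale_factor: float = 1.25,
    min_scale: float = 1.0,
    max_scale: float | None = None,
) -> list[float]:
    """Scales s (window size in original pixels = s * window) largest-first excluded; ascending."""
    if scale_factor <= 1.0:
        raise ValueError("scale_factor must be > 1")
    scales = []
    s = min_scale
    while (
        int(round(img_h / s)) >= window_h
        and int(round(img_w / s)) >= window_w
        and (max_scale is None or s <= max_scale)
    ):
        scales.append(s)
        s *= scale_factor
    return scales


def sliding_windows(
    img: np.ndarray,
    window_h: int,
    window_w: int,
    stride: int = 1,
    scale_factor: float = 1.25,
    min_scale: float = 1.0,
    max_scale: float | None = None,
) -> Iterator[tuple[Rect, np.ndarray, float]]:
    """Yield ``(rect, window, scale)`` over an image pyramid in raster order.

    ``rect`` is in original-image coordinates; ``window`` is the
    ``(window_h, window_w)`` patch cut from the downscaled level. An image
    smaller than the window at every admissible scale yields nothing.
    """
    arr = as_gray_image(img)
    if stride < 1:
        raise ValueError("stride must be >= 1")
    H, W = arr.shape
    for s in pyramid_scales(H, W, window_h, window_w, scale_factor, min_scale, max_scale):
        hs, ws = int(round(H / s)), int(round(W / s))
        level = arr if s == 1.0 else resize(
            arr, (hs, ws), anti_aliasing=True, preserve_range=True
        )
        for y in range(0, hs - window_h + 1, stride):
            for x in range(0, ws - window_w + 1, stride):
                ry, rx = int(round(y * s)), int(round(x * s))
                rh = min(int(round(window_h * s)), H - ry)
                rw = min(int(round(window_w * s)), W - rx)
                yield Rect(ry, rx, rh, rw), level[y : y + window_h, x : x + window_w], s


def nms(detections: Sequence[Detection], iou_threshold: float = 0.3) -> list[Detection]:
    """Greedy score-descending non-maximum suppression."""
    order = sorted(detections, key=lambda d: -d.score)
    kept: list[Detection] = []
    for d in order:
        if all(iou(d.rect, k.rect) <= iou_threshold for k in kept):
            kept.append(d)
    return kept


def detect(
    m: CascadeModel,
    img: np.ndarray,
    extractor: Extractor | None = None,
    stride: int = 1,
    scale_factor: float = 1.25,
    min_scale: float = 1.0,
    max_scale: float | None = None,
    use_nms: bool = True,
    nms_iou: float = 0.3,
    return_stats: bool = False,
):
    """Run a cascade over a whole image; return accepted windows.

    The extractor defaults to the one recorded in the model's
    ``feature_config``. With ``return_stats=True`` also returns
    ``{"n_windows", "mean_stages_evaluated"}`` — early rejection keeps the
    mean well under the stage count on background-dominated scenes.
    """
    if extractor is None:
        extractor = build_extractor(m.feature_config)[0]
    n_stages = m.n_stages if m.kind == "hard" else len(m.stages[0].stumps)
    rects: list[Rect] = []
    wins: list[np.ndarray] = []
    scales: list[float] = []
    for r, w, s in sliding_windows(
        img, m.window_h, m.window_w, stride, scale_factor, min_scale, max_scale
    ):
        rects.append(r)
        wins.append(w)
        scales.append(s)
    detections: list[Detection] = []
    total_evals = 0
    if wins:
        X = extractor(wins)
        acc, passed, margin = m.classify_batch(X)
        # stages evaluated = stages passed, plus the rejecting stage if any
        total_evals = int(np.sum(np.minimum(passed + (~acc), n_stages)))
        for i in np.flatnonzero(acc):
            detections.append(Detection(rect=rects[i], score=float(margin[i]), scale=scales[i]))
    if use_nms:
        detections = nms(detections, nms_iou)
    if return_stats:
        stats = {
            "n_windows": len(wins),
            "mean_stages_evaluated": total_evals / len(wins) if wins else 0.0,
        }
        return detections, stats
    return detections


def detections_to_csv(detections: Sequence[Detection], path, image_id: str = "") -> None:
    """Write detections as CSV (image_id, y, x, h, w, score, scale)."""
    import pandas as pd

    pd.DataFrame(
        [
            {
                "image_id": image_id,
                "y": d.rect.y,
                "x": d.rect.x,
                "h": d.rect.h,
                "w": d.rect.w,
                "score": d.score,
                "scale": d.scale,
            }
            for d in detections
        ],
        columns=["image_id", "y", "x", "h", "w", "score", "scale"],
    ).to_csv(path, index=False)


def draw_overlay(img: np.ndarray, detections: Sequence[Detection], path) -> None:
    """Write the image with white detection outlines as a PNG."""
    from .image import save_gray

    canvas = np.asarray(img, dtype=float).copy()
    H, W = canvas.shape
    for d in detections:
        r = d.rect
        y1, x1 = min(r.y + r.h - 1, H - 1), min(r.x + r.w - 1, W - 1)
        canvas[r.y, r.x : x1 + 1] = 255
        canvas[y1, r.x : x1 + 1] = 255
        canvas[r.y : y1 + 1, r.x] = 255
        canvas[r.y : y1 + 1, x1] = 255
    save_gray(path, canvas)
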