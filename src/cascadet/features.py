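"""Feature-extractor configuration shared by training, detection and the CLI.

A feature configuration is a plain serialisable dict (it travels inside
the cascade model file) naming the family and its parameters:

* ``{"kind": "haar", "window": [h, w], "stride": s, "scale_step": c}``
* ``{"kind": "texture", "window": [h, w], "distances": [...],
  "angles": [...], "levels": n, "hist_levels": n, "mode": "standard"}``

:func:`build_extractor` turns a configuration into a callable mapping a
stack of window-sized grayscale images to the feature matrix.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

from . import haar, texture

Extractor = Callable[[Sequence[np.ndarray]], np.ndarray]


def haar_config(
    window_h: int, window_w: int, stride: int = 1, scale_step: int = 1
) -> dict:
    return {
        "kind": "haar",
        "window": [int(window_h), int(window_w)],
        "stride": int(stride),
        "scale_step": int(scale_step),
    }


def texture_config(
    window_h: int,
    window_w: int,
    distances: Sequence[int] = texture.DEFAULT_DISTANCES,
    angles: Sequence[int] = texture.DEFAULT_ANGLES,
    levels: int = texture.DEFAULT_GLCM_LEVELS,
    hist_levels: int = texture.DEFAULT_HIST_LEVELS,
    mode: str = "standard",
) -> dict:
    return {
        "kind": "texture",
        "window": [int(window_h), int(window_w)],
        "distances": [int(d) for d in distances],
        "angles": [int(a) for a in angles],
        "levels": int(levels),
        "hist_levels": int(hist_levels),
        "mode": mode,
    }


def build_extractor(fc: dict) -> tuple[Extractor, int]:
    """Compile a feature configuration into ``(extract_fn, n_features)``."""
    kind = fc.get("kind")
    h, w = fc["window"]
    if kind == "haar":
        feats = haar.enumerate_haar(h, w, fc.get("stride", 1), fc.get("scale_step", 1))

        def extract(imgs: Sequence[np.ndarray]) -> np.ndarray:
            return haar.extract_haar_matrix(imgs, feats)

        return extract, len(feats)
    if kind == "texture":
        distances = fc.get("distances", list(texture.DEFAULT_DISTANCES))
        angles = fc.get("angles", list(texture.DEFAULT_ANGLES))
        # drop distances no pair fits in the window
        usable = [d for d in distances if d < min(h, w)]

        def extract(imgs: Sequence[np.ndarray]) -> np.ndarray:
            return texture.extract_texture_matrix(
                imgs,
                distances=usable,
                angles=angles,
                levels=fc.get("levels", texture.DEFAULT_GLCM_LEVELS),
                hist_levels=fc.get("hist_levels", texture.DEFAULT_HIST_LEVELS),
                mode=fc.get("mode", "standard"),
            )

        n = len(texture.FIRST_ORDER_NAMES) + len(texture.HARALICK_NAMES) * len(angles) * len(usable)
        return extract, n
    raise ValueError(f"unknown feature kind {kind!r}")


def feature_names(fc: dict) -> list[str]:
    """Column names of the extracted feature matrix."""
    kind = fc.get("kind")
    h, w = fc["window"]
    if kind == "haar":
        feats = haar.enumerate_haar(h, w, fc.get("stride", 1), fc.get("scale_step", 1))
        return [
            f"haar_{f.kind.value}_y{f.base_rect.y}_x{f.base_rect.x}"
            f"_h{f.base_rect.h}_w{f.base_rect.w}"
            for f in feats
        ]
    if kind == "texture":
        distances = [d for d in fc.get("distances", texture.DEFAULT_DISTANCES) if d < min(h, w)]
        angles = fc.get("angles", texture.DEFAULT_ANGLES)
        return texture.texture_feature_names(distances, angles)
    raise ValueError(f"unknown feature kind {kind!r}")


def write_feature_csv(path, X: np.ndarray, fc: dict) -> None:
    """Write a feature matrix as CSV with one named column per statistic."""
    import pandas as pd

    pd.DataFrame(np.atleast_2d(X), columns=feature_names(fc)).to_csv(path, index=False)
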