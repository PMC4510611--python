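"""First- and second-order statistical texture features.

First-order statistics are 13 scalars of the normalised intensity
histogram (mean, mode, variance, quartiles, interquartile range, min,
max, value range, entropy, asymmetry/skewness, kurtosis). Second-order
statistics are 19 Haralick-style coefficients of the gray-level
co-occurrence matrix (GLCM), computed at four angles
{0, 45, 90, 135} degrees and a configurable set of pixel distances
(default {1, 3, 5, 10, 15}).

Two formula variants of the Haralick set are exposed:

* ``mode="standard"`` (default) — the conventional definitions: variances
  are true central moments, entropies are non-negative, the correlation
  denominator uses standard deviations, and the second information
  measure of correlation takes the square root.
* ``mode="paper"`` — a literal transcription of a commonly printed table
  of the formulas, in which sum variance carries a leading minus and is
  centred on sum entropy, difference variance is a raw second moment,
  sum entropy lacks its minus sign, the correlation denominator holds
  variances, and the second information measure omits the square root.

All logarithms are natural; ``0 * log 0`` is taken as 0.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Iterable, Sequence

import numpy as np

from .image import as_gray_image

DEFAULT_ANGLES = (0, 45, 90, 135)
DEFAULT_DISTANCES = (1, 3, 5, 10, 15)
DEFAULT_GLCM_LEVELS = 32
DEFAULT_HIST_LEVELS = 256

#: displacement (dy, dx) per angle, for unit distance
_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}

FIRST_ORDER_NAMES = (
    "mean", "mode", "variance", "q1", "q2", "q3", "iqr", "minimum",
    "maximum", "value_range", "entropy", "asymmetry", "kurtosis",
)
HARALICK_NAMES = (
    "energy", "correlation", "contrast", "variance", "sum_average",
    "sum_entropy", "sum_variance", "entropy", "difference_variance",
    "difference_entropy", "corr_info_1", "corr_info_2", "homogeneity_1",
    "homogeneity_2", "cluster_shade", "cluster_prominence",
    "autocorrelation", "dissimilarity", "max_probability",
)


@dataclass(frozen=True)
class HistogramStats:
    mean: float
    mode: float
    variance: float
    q1: float
    q2: float
    q3: float
    iqr: float
    minimum: float
    maximum: float
    value_range: float
    entropy: float
    asymmetry: float
    kurtosis: float
    flags: tuple[str, ...] = ()

    def as_vector(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FIRST_ORDER_NAMES])


@dataclass(frozen=True)
class GlcmSpec:
    """Parameters of one co-occurrence matrix.

    ``angle`` in degrees (0, 45, 90 or 135); ``distance`` in pixels.
    ``symmetric`` accumulates both displacement directions; ``normalized``
    scales entries to sum to one.
    """

    angle: int
    distance: int
    levels: int = DEFAULT_GLCM_LEVELS
    symmetric: bool = True
    normalized: bool = True

    def __post_init__(self) -> None:
        if self.angle not in _OFFSETS:
            raise ValueError(f"angle must be one of {sorted(_OFFSETS)}, got {self.angle}")
        if self.distance < 1:
            raise ValueError("distance must be >= 1")
        if self.levels < 2:
            raise ValueError("levels must be >= 2")

    @property
    def offset(self) -> tuple[int, int]:
        dy, dx = _OFFSETS[self.angle]
        return dy * self.distance, dx * self.distance


@dataclass(frozen=True)
class HaralickStats:
    energy: float
    correlation: float
    contrast: float
    variance: float
    sum_average: float
    sum_entropy: float
    sum_variance: float
    entropy: float
    difference_variance: float
    difference_entropy: float
    corr_info_1: float
    corr_info_2: float
    homogeneity_1: float
    homogeneity_2: float
    cluster_shade: float
    cluster_prominence: float
    autocorrelation: float
    dissimilarity: float
    max_probability: float
    flags: tuple[str, ...] = ()

    def as_vector(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in HARALICK_NAMES])


def quantize(img: np.ndarray, levels: int, intensity_range: float = 256.0) -> np.ndarray:
    """Linearly bin intensities from ``[0, intensity_range)`` into ``levels``."""
    arr = as_gray_image(img)
    q = np.floor(np.asarray(arr, dtype=np.float64) / intensity_range * levels)
    return np.clip(q, 0, levels - 1).astype(np.intp)


def histogram(img: np.ndarray, levels: int = DEFAULT_HIST_LEVELS) -> np.ndarray:
    """Normalised histogram over quantized gray levels (sums to 1)."""
    if levels < 2:
        raise ValueError("levels must be >= 2")
    q = quantize(img, levels)
    counts = np.bincount(q.ravel(), minlength=levels).astype(np.float64)
    return counts / counts.sum()


def _entropy(p: np.ndarray) -> float:
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def first_order_stats(h: np.ndarray) -> HistogramStats:
    """The 13 first-order statistics of a normalised histogram.

    Quartiles are intensity quantiles: the smallest level whose cumulative
    probability reaches 0.25 / 0.5 / 0.75. For a degenerate (zero-variance)
    histogram, asymmetry and kurtosis are returned as 0 with a
    ``"degenerate_variance"`` flag.
    """
    h = np.asarray(h, dtype=np.float64)
    if h.size == 0 or not np.isclose(h.sum(), 1.0):
        raise ValueError("histogram must be non-empty and normalised")
    levels = np.arange(h.size, dtype=np.float64)
    mean = float(levels @ h)
    mode = float(np.argmax(h))
    variance = float(((levels - mean) ** 2) @ h)
    cum = np.cumsum(h)
    q1, q2, q3 = (float(np.searchsorted(cum, q)) for q in (0.25, 0.5, 0.75))
    nonzero = np.flatnonzero(h > 0)
    minimum, maximum = float(nonzero[0]), float(nonzero[-1])
    flags: tuple[str, ...] = ()
    sigma = np.sqrt(variance)
    if sigma > 0:
        asym = float(((levels - mean) ** 3) @ h / sigma**3)
        kurt = float(((levels - mean) ** 4) @ h / sigma**4)
    else:
        asym = kurt = 0.0
        flags = ("degenerate_variance",)
    return HistogramStats(
        mean=mean, mode=mode, variance=variance, q1=q1, q2=q2, q3=q3,
        iqr=q3 - q1, minimum=minimum, maximum=maximum,
        value_range=maximum - minimum, entropy=_entropy(h),
        asymmetry=asym, kurtosis=kurt, flags=flags,
    )


def glcm(img: np.ndarray, spec: GlcmSpec) -> np.ndarray:
    """Gray-level co-occurrence matrix of an image under ``spec``.

    Entry ``(i, j)`` counts ordered pixel pairs with quantized levels
    ``i`` at a reference position and ``j`` at the position displaced by
    the spec's (angle, distance) offset.
    """
    q = quantize(img, spec.levels)
    dy, dx = spec.offset
    H, W = q.shape
    if abs(dy) >= H or abs(dx) >= W:
        raise ValueError(
            f"window {H}x{W} too small for distance {spec.distance} at angle {spec.angle}"
        )
    ys = slice(max(0, -dy), min(H, H - dy))
    xs = slice(max(0, -dx), min(W, W - dx))
    a = q[ys, xs]
    b = q[ys.start + dy : ys.stop + dy, xs.start + dx : xs.stop + dx]
    idx = a.ravel() * spec.levels + b.ravel()
    p = np.bincount(idx, minlength=spec.levels**2).astype(np.float64)
    p = p.reshape(spec.levels, spec.levels)
    if spec.symmetric:
        p = p + p.T
    if spec.normalized:
        p = p / p.sum()
    return p


def haralick_stats(p: np.ndarray, mode: str = "standard") -> HaralickStats:
    """The 19 second-order statistics of a normalised GLCM ``p``."""
    if mode not in ("standard", "paper"):
        raise ValueError(f"mode must be 'standard' or 'paper', got {mode!r}")
    p = np.asarray(p, dtype=np.float64)
    if p.ndim != 2 or p.shape[0] != p.shape[1]:
        raise ValueError("GLCM must be a square matrix")
    if not np.isclose(p.sum(), 1.0, atol=1e-9):
        raise ValueError("GLCM must be normalised (sum to 1)")
    n = p.shape[0]
    i = np.arange(n, dtype=np.float64)[:, None]
    j = np.arange(n, dtype=np.float64)[None, :]
    px, py = p.sum(axis=1), p.sum(axis=0)
    mu_x, mu_y = float(px @ np.arange(n)), float(py @ np.arange(n))
    var_x = float(px @ (np.arange(n) - mu_x) ** 2)
    var_y = float(py @ (np.arange(n) - mu_y) ** 2)
    flags: list[str] = []

    # marginal distributions of i+j and |i-j|
    k_sum = np.arange(2 * n - 1, dtype=np.float64)
    p_sum = np.bincount(
        (np.arange(n)[:, None] + np.arange(n)[None, :]).ravel(),
        weights=p.ravel(), minlength=2 * n - 1,
    )
    k_diff = np.arange(n, dtype=np.float64)
    p_diff = np.bincount(
        np.abs(np.arange(n)[:, None] - np.arange(n)[None, :]).ravel(),
        weights=p.ravel(), minlength=n,
    )

    energy = float((p**2).sum())
    contrast = float(((i - j) ** 2 * p).sum())
    autocorr = float((i * j * p).sum())
    denom = var_x * var_y if mode == "paper" else np.sqrt(var_x * var_y)
    if denom > 0:
        correlation = (autocorr - mu_x * mu_y) / denom
    else:
        correlation = 0.0
        flags.append("correlation_denominator_zero")
    variance = float(((i - mu_x) ** 2 * p).sum())
    sum_average = float(k_sum @ p_sum)
    se_std = _entropy(p_sum)
    sum_entropy = -se_std if mode == "paper" else se_std
    if mode == "paper":
        sum_variance = -float(((k_sum - sum_entropy) ** 2) @ p_sum)
    else:
        sum_variance = float(((k_sum - sum_average) ** 2) @ p_sum)
    entropy = _entropy(p)
    if mode == "paper":
        difference_variance = float((k_diff**2) @ p_diff)
    else:
        mu_d = float(k_diff @ p_diff)
        difference_variance = float(((k_diff - mu_d) ** 2) @ p_diff)
    difference_entropy = _entropy(p_diff)

    hx, hy = _entropy(px), _entropy(py)
    pxy = px[:, None] * py[None, :]
    nz = p > 0
    hxy1 = float(-(p[nz] * np.log(pxy[nz])).sum())
    hxy2 = _entropy(pxy.ravel())
    hmax = max(hx, hy)
    if hmax > 0:
        corr_info_1 = (entropy - hxy1) / hmax
    else:
        corr_info_1 = 0.0
        flags.append("corr_info_1_denominator_zero")
    raw2 = 1.0 - np.exp(-2.0 * (hxy2 - entropy))
    corr_info_2 = float(raw2) if mode == "paper" else float(np.sqrt(max(raw2, 0.0)))

    return HaralickStats(
        energy=energy, correlation=float(correlation), contrast=contrast,
        variance=variance, sum_average=sum_average, sum_entropy=float(sum_entropy),
        sum_variance=float(sum_variance), entropy=entropy,
        difference_variance=difference_variance,
        difference_entropy=difference_entropy, corr_info_1=float(corr_info_1),
        corr_info_2=corr_info_2,
        homogeneity_1=float((p / (1.0 + (i - j) ** 2)).sum()),
        homogeneity_2=float((p / (1.0 + np.abs(i - j))).sum()),
        cluster_shade=float(((i + j - mu_x - mu_y) ** 3 * p).sum()),
        cluster_prominence=float(((i + j - mu_x - mu_y) ** 4 * p).sum()),
        autocorrelation=autocorr,
        dissimilarity=float((np.abs(i - j) * p).sum()),
        max_probability=float(p.max()), flags=tuple(flags),
    )


def texture_feature_names(
    distances: Sequence[int] = DEFAULT_DISTANCES,
    angles: Sequence[int] = DEFAULT_ANGLES,
) -> list[str]:
    """Column names matching :func:`extract_texture_vector` order."""
    names = [f"hist_{n}" for n in FIRST_ORDER_NAMES]
    for a in angles:
        for d in distances:
            names += [f"glcm_a{a}_d{d}_{n}" for n in HARALICK_NAMES]
    return names


def extract_texture_vector(
    img: np.ndarray,
    distances: Sequence[int] = DEFAULT_DISTANCES,
    angles: Sequence[int] = DEFAULT_ANGLES,
    levels: int = DEFAULT_GLCM_LEVELS,
    hist_levels: int = DEFAULT_HIST_LEVELS,
    mode: str = "standard",
) -> np.ndarray:
    """13 first-order + 19 Haralick statistics per (angle, distance).

    Order: first-order block, then angles in the given order, distances
    inner; default configuration yields 13 + 19*4*5 = 393 entries.
    """
    parts = [first_order_stats(histogram(img, hist_levels)).as_vector()]
    for a in angles:
        for d in distances:
            p = glcm(img, GlcmSpec(angle=a, distance=d, levels=levels))
            parts.append(haralick_stats(p, mode=mode).as_vector())
    return np.concatenate(parts)


def extract_texture_matrix(
    imgs: Iterable[np.ndarray],
    distances: Sequence[int] = DEFAULT_DISTANCES,
    angles: Sequence[int] = DEFAULT_ANGLES,
    levels: int = DEFAULT_GLCM_LEVELS,
    hist_levels: int = DEFAULT_HIST_LEVELS,
    mode: str = "standard",
) -> np.ndarray:
    return np.stack([
        extract_texture_vector(im, distances, angles, levels, hist_levels, mode)
        for im in imgs
    ])
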