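"""Synthetic patch datasets and scenes for training and benchmarking.

The generator emulates the patch-classification setting of face,
pedestrian and mammographic-lesion detection corpora: positives are small
grayscale windows holding one centred object (Gaussian blob, oriented bar
or annulus) over a heterogeneous background; negatives are background-only
windows. Intensities live on the 8-bit scale [0, 255].

Class separability is controlled by a single ``overlap`` knob in [0, 1]:
the planted object's amplitude is ``contrast * (1 - overlap)``, so
``overlap=0`` gives near-separable classes and ``overlap=1`` makes the
positive and negative generative laws identical. Backgrounds can be flat,
linear ramps, or smoothed-noise clutter (the clutter carries spatial
correlation, so co-occurrence texture statistics are informative on it,
while blobs/bars separate under Haar-like features).

All randomness flows through one seeded generator; a fixed seed yields
byte-identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .image import Rect, save_gray

OBJECT_KINDS = ("blob", "bar", "ring")
BACKGROUND_KINDS = ("flat", "gradient", "clutter")


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of one synthetic patch dataset.

    ``contrast`` is the peak object amplitude in intensity units at
    ``overlap=0``; ``noise_sd`` the per-pixel Gaussian noise level;
    ``overlap`` the class-overlap knob described in the module docstring.
    """

    n_pos: int = 200
    n_neg: int = 2000
    window_h: int = 16
    window_w: int = 16
    object_kind: str = "blob"
    contrast: float = 60.0
    noise_sd: float = 20.0
    background_kind: str = "clutter"
    overlap: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 2:
            raise ValueError("n_pos must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0.0 <= self.overlap <= 1.0):
            raise ValueError("overlap must be in [0, 1]")
        if self.object_kind not in OBJECT_KINDS:
            raise ValueError(f"object_kind must be one of {OBJECT_KINDS}")
        if self.background_kind not in BACKGROUND_KINDS:
            raise ValueError(f"background_kind must be one of {BACKGROUND_KINDS}")


def _background(rng: np.random.Generator, h: int, w: int, kind: str) -> np.ndarray:
    base = rng.uniform(96.0, 160.0)
    img = np.full((h, w), base)
    if kind == "gradient":
        theta = rng.uniform(0.0, 2.0 * np.pi)
        amp = rng.uniform(10.0, 50.0)
        yy, xx = np.mgrid[0:h, 0:w]
        proj = (yy / max(h - 1, 1)) * np.sin(theta) + (xx / max(w - 1, 1)) * np.cos(theta)
        img = img + amp * (proj - proj.mean())
    elif kind == "clutter":
        noise = rng.normal(0.0, 1.0, (h, w))
        smooth = ndimage.gaussian_filter(noise, sigma=min(h, w) / 8.0)
        sd = smooth.std()
        if sd > 0:
            img = img + (smooth - smooth.mean()) / sd * 25.0
    return img


def _object_mask(rng: np.random.Generator, h: int, w: int, kind: str) -> np.ndarray:
    """Unit-peak object profile, centred with mild position/shape jitter."""
    cy = (h - 1) / 2.0 + rng.uniform(-0.1, 0.1) * h
    cx = (w - 1) / 2.0 + rng.uniform(-0.1, 0.1) * w
    yy, xx = np.mgrid[0:h, 0:w]
    m = min(h, w)
    if kind == "blob":
        sigma = m / 5.0 * rng.uniform(0.8, 1.2)
        mask = np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * sigma**2)))
    elif kind == "bar":
        theta = rng.uniform(0.0, np.pi)
        sigma = m / 8.0 * rng.uniform(0.8, 1.2)
        dist = (yy - cy) * np.cos(theta) - (xx - cx) * np.sin(theta)
        mask = np.exp(-(dist**2) / (2.0 * sigma**2))
    else:  # ring
        r0 = m / 4.0 * rng.uniform(0.9, 1.1)
        sigma = m / 10.0
        r = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
        mask = np.exp(-((r - r0) ** 2) / (2.0 * sigma**2))
    return mask


def _render_patch(
    rng: np.random.Generator, cfg: SynthConfig, h: int, w: int, with_object: bool
) -> np.ndarray:
    img = _background(rng, h, w, cfg.background_kind)
    # the object branch consumes identical rng draws either way, so that at
    # overlap=1 positives and negatives share one generative law exactly
    amp = cfg.contrast * (1.0 - cfg.overlap)
    mask = _object_mask(rng, h, w, cfg.object_kind)
    if with_object:
        img = img + amp * mask
    if cfg.noise_sd > 0:
        img = img + rng.normal(0.0, cfg.noise_sd, (h, w))
    return np.clip(img, 0.0, 255.0)


def generate_patches(cfg: SynthConfig) -> tuple[np.ndarray, np.ndarray]:
    """Positive and negative patch stacks, fully determined by ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.window_h, cfg.window_w
    pos = np.stack([_render_patch(rng, cfg, h, w, True) for _ in range(cfg.n_pos)])
    neg = np.stack([_render_patch(rng, cfg, h, w, False) for _ in range(cfg.n_neg)])
    return pos, neg


def generate_scene(
    cfg: SynthConfig,
    n_objects: int,
    scene_h: int,
    scene_w: int,
    max_tries: int = 200,
) -> tuple[np.ndarray, list[Rect]]:
    """A background canvas with non-overlapping planted objects.

    Objects are rendered at scales 1-1.5x the configured window and placed
    uniformly, rejecting overlaps; raises ``RuntimeError`` if a placement
    cannot be found within ``max_tries`` attempts. Returns the scene and
    the ground-truth rectangles.
    """
    rng = np.random.default_rng(cfg.seed)
    scene = _background(rng, scene_h, scene_w, cfg.background_kind)
    amp = cfg.contrast * (1.0 - cfg.overlap)
    truths: list[Rect] = []
    for _ in range(n_objects):
        placed = False
        for _ in range(max_tries):
            s = rng.uniform(1.0, 1.5)
            h = int(round(cfg.window_h * s))
            w = int(round(cfg.window_w * s))
            if h > scene_h or w > scene_w:
                continue
            y = int(rng.integers(0, scene_h - h + 1))
            x = int(rng.integers(0, scene_w - w + 1))
            cand = Rect(y, x, h, w)
            if all(_iou(cand, t) == 0.0 for t in truths):
                scene[y : y + h, x : x + w] += amp * _object_mask(rng, h, w, cfg.object_kind)
                truths.append(cand)
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"could not place object {len(truths) + 1}/{n_objects} "
                f"without overlap in {max_tries} tries"
            )
    if cfg.noise_sd > 0:
        scene = scene + rng.normal(0.0, cfg.noise_sd, scene.shape)
    return np.clip(scene, 0.0, 255.0), truths


def _iou(a: Rect, b: Rect) -> float:
    y0, x0 = max(a.y, b.y), max(a.x, b.x)
    y1, x1 = min(a.y + a.h, b.y + b.h), min(a.x + a.w, b.x + b.w)
    inter = max(0, y1 - y0) * max(0, x1 - x0)
    if inter == 0:
        return 0.0
    return inter / (a.area + b.area - inter)


#: difficulty tiers of the standard benchmark: class-overlap per tier
BENCHMARK_TIERS = {"easy": 0.0, "medium": 0.3, "hard": 0.6}


def benchmark_suite(seed: int = 0) -> dict:
    """Three-tier standard benchmark (easy/medium/hard by class overlap).

    Each tier holds 200 positive patches, a 2000-negative pool (the
    10x imbalance of detection corpora) and one 96x96 scene with three
    planted objects. Deterministic under ``seed``.
    """
    ss = np.random.SeedSequence(seed)
    tier_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(BENCHMARK_TIERS))]
    suite = {}
    for (name, overlap), tseed in zip(BENCHMARK_TIERS.items(), tier_seeds):
        cfg = SynthConfig(n_pos=200, n_neg=2000, overlap=overlap, seed=tseed)
        pos, neg = generate_patches(cfg)
        scene, truths = generate_scene(replace(cfg, seed=tseed + 1), 3, 96, 96)
        suite[name] = {
            "config": cfg,
            "positives": pos,
            "negatives": neg,
            "scene": scene,
            "scene_truth": truths,
        }
    return suite


def write_patch_dirs(out_dir, pos: np.ndarray, neg: np.ndarray) -> None:
    """Write patches in the pos/ neg/ PNG layout the trainer consumes."""
    out = Path(out_dir)
    for sub, stack in (("pos", pos), ("neg", neg)):
        d = out / sub
        d.mkdir(parents=True, exist_ok=True)
        for i, img in enumerate(stack):
            save_gray(d / f"{sub}_{i:05d}.png", img)
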