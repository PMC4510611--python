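"""ROC construction, partial AUC, and cross-validated detector comparison.

A hard cascade emits a binary decision, so its ROC is swept with a scalar
ranking score that refines that decision monotonically: the number of
stages a sample passes plus a logistic squash of its exit margin. Samples
accepted by the whole cascade always outrank rejected ones, and within a
rejection depth the stage margin breaks ties.

The headline summary statistic is the partial area under the ROC curve
(pAUC) over the low false-positive interval FPr in [0, fpr_max]
(default 0.5, the random-guessing error of a two-class problem); it is
reported unnormalised, so a perfect detector scores ``fpr_max``.
Detectors are compared by stratified k-fold cross-validation (default
k=10) reporting the across-fold mean and sample standard deviation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedKFold

from .cascade import CascadeModel, NegativePool, TrainConfig, train_cascade

TrainerFn = Callable[[np.ndarray, np.ndarray, int], CascadeModel]


@dataclass(frozen=True)
class RocCurve:
    """Operating points (FPr, TPr), both non-decreasing from (0,0) to (1,1)."""

    fpr: np.ndarray
    tpr: np.ndarray


@dataclass(frozen=True)
class PaucSummary:
    """Cross-validated pAUC: per-fold values, their mean and sample SD."""

    per_fold: tuple[float, ...]
    fpr_max: float

    @property
    def mean(self) -> float:
        return float(np.mean(self.per_fold))

    @property
    def sigma(self) -> float:
        return float(np.std(self.per_fold, ddof=1)) if len(self.per_fold) > 1 else 0.0

    @property
    def pauc(self) -> float:
        return self.mean


def cascade_ranking_score(m: CascadeModel, X: np.ndarray) -> np.ndarray:
    """Scalar ranking score, monotone in (stages passed, exit margin)."""
    _, passed, margin = m.classify_batch(X)
    return passed + 1.0 / (1.0 + np.exp(-np.clip(margin, -500, 500)))


def roc_from_scores(scores_pos: Sequence[float], scores_neg: Sequence[float]) -> RocCurve:
    """Standard threshold-sweep ROC (ties step diagonally)."""
    sp, sn = np.asarray(scores_pos, dtype=float), np.asarray(scores_neg, dtype=float)
    if sp.size == 0 or sn.size == 0:
        raise ValueError("both score lists must be non-empty")
    y = np.concatenate([np.ones(sp.size), np.zeros(sn.size)])
    fpr, tpr, _ = _sk_roc_curve(y, np.concatenate([sp, sn]), drop_intermediate=False)
    if fpr[-1] != 1.0 or tpr[-1] != 1.0:  # defensive; sweep always ends at (1,1)
        fpr, tpr = np.append(fpr, 1.0), np.append(tpr, 1.0)
    return RocCurve(fpr=fpr, tpr=tpr)


def partial_auc(roc: RocCurve, fpr_max: float = 0.5) -> float:
    """Trapezoidal area of the ROC restricted to FPr in [0, fpr_max].

    The right boundary is linearly interpolated; ``fpr_max=1`` recovers
    the full AUC (the normalised Mann-Whitney U statistic).
    """
    if not (0.0 < fpr_max <= 1.0):
        raise ValueError("fpr_max must be in (0, 1]")
    fpr, tpr = roc.fpr, roc.tpr
    keep = fpr < fpr_max
    # right-boundary TPr: approach from the left so that a vertical jump
    # exactly at fpr_max contributes no area
    i = int(np.searchsorted(fpr, fpr_max, side="left"))
    if fpr[i] == fpr_max:
        ytail = tpr[i]
    else:
        frac = (fpr_max - fpr[i - 1]) / (fpr[i] - fpr[i - 1])
        ytail = tpr[i - 1] + frac * (tpr[i] - tpr[i - 1])
    x = np.append(fpr[keep], fpr_max)
    return float(np.trapezoid(np.append(tpr[keep], ytail), x))


def _fold_seeds(seed: int, k: int) -> list[int]:
    return [int(s % (2**31)) for s in np.random.SeedSequence(seed).generate_state(k)]


def kfold_cv(
    X: np.ndarray,
    y: np.ndarray,
    trainer: TrainerFn,
    k: int = 10,
    seed: int = 0,
    fpr_max: float = 0.5,
) -> PaucSummary:
    """Stratified k-fold pAUC of a detector trainer.

    ``trainer(X_pos, X_neg, seed) -> CascadeModel`` is called once per
    fold on the training split; the held-out fold is ranked with
    :func:`cascade_ranking_score`. Labels ``y`` are +/-1. Each sample is
    tested exactly once; folds and trainer seeds derive from ``seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if k < 2:
        raise ValueError("k must be >= 2")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_seeds = _fold_seeds(seed, k)
    per_fold = []
    for fseed, (tr, te) in zip(fold_seeds, skf.split(X, y)):
        ytr, yte = y[tr], y[te]
        if len(np.unique(ytr)) < 2 or len(np.unique(yte)) < 2:
            raise ValueError("a fold lost one class entirely; use fewer folds")
        model = trainer(X[tr][ytr > 0], X[tr][ytr < 0], fseed)
        scores = cascade_ranking_score(model, X[te])
        roc = roc_from_scores(scores[yte > 0], scores[yte < 0])
        per_fold.append(partial_auc(roc, fpr_max))
    return PaucSummary(per_fold=tuple(per_fold), fpr_max=fpr_max)


def cascade_trainer(cfg: TrainConfig) -> TrainerFn:
    """Adapt a :class:`TrainConfig` into the ``kfold_cv`` trainer signature."""

    def train(X_pos: np.ndarray, X_neg: np.ndarray, seed: int) -> CascadeModel:
        pool = NegativePool(X_neg)
        return train_cascade(X_pos, pool, dataclasses.replace(cfg, seed=seed))

    return train


def compare_detectors(
    X: np.ndarray,
    y: np.ndarray,
    configs: Sequence[tuple[str, TrainerFn]],
    k: int = 10,
    seeds: Sequence[int] = (0,),
    fpr_max: float = 0.5,
) -> pd.DataFrame:
    """Mean pAUC +/- sigma per detector over k-fold CV and several seeds.

    ``configs`` is a list of ``(name, trainer)`` pairs. The returned frame
    has one row per detector: pAUC averaged over seeds, the across-fold
    standard deviation averaged over seeds, and per-seed detail columns.
    """
    if len(configs) < 2:
        raise ValueError("need at least 2 detector configs to compare")
    rows = []
    for name, trainer in configs:
        summaries = [kfold_cv(X, y, trainer, k=k, seed=s, fpr_max=fpr_max) for s in seeds]
        rows.append({
            "detector": name,
            "pauc": float(np.mean([s.mean for s in summaries])),
            "sigma": float(np.mean([s.sigma for s in summaries])),
            "n_seeds": len(seeds),
            "k": k,
            "fpr_max": fpr_max,
            "per_seed_pauc": [s.mean for s in summaries],
            "per_seed_sigma": [s.sigma for s in summaries],
        })
    return pd.DataFrame(rows)


def plot_roc(rocs: dict[str, RocCurve], path, fpr_max: float | None = None) -> None:
    """Plot one or more ROC curves to a PNG/SVG file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for name, roc in rocs.items():
        ax.plot(roc.fpr, roc.tpr, label=name)
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    if fpr_max is not None:
        ax.axvline(fpr_max, color="gray", lw=0.8, ls="--")
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
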