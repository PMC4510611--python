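"""Cascade detectors with boundary-proximal hard-negative selection.

A cascade is a sequence of boosted stage classifiers; a sample is labelled
positive only if every stage accepts it. Under stage independence the
global detection and false-positive rates factor into products of the
per-stage rates, so driving each stage's false-positive rate below ``f``
(while keeping its detection rate above ``d``) shrinks the global
false-positive rate geometrically.

The trainer here balances every stage: the negative training set always
has the size of the positive set, drawn from a pool of accumulated false
positives. Two selection rules are provided:

* ``confidence`` — take the false positives with the *smallest* margin at
  the newest stage, i.e. the samples closest to the decision boundary.
  Near the boundary the classifier's output is uninformative (random
  guessing), which decouples the next stage from the current cascade and
  pushes the stages toward independence.
* ``random`` — uniform selection from the pool, the classic bootstrap
  baseline; identical machinery otherwise.

The first stage always uses random selection (no earlier stage exists to
provide confidences). A simplified soft cascade — one long boosted stage
with per-prefix rejection thresholds calibrated on positive partial
scores — is included as a second baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml

from .boosting import (
    DecisionStump,
    StageClassifier,
    StumpFitter,
    adaboost_train,
    boost_round,
    decrement_threshold,
)

FORMAT_VERSION = 1


class ModelFormatError(ValueError):
    """Raised when a model file cannot be parsed or has the wrong schema."""


@dataclass
class TrainConfig:
    """Cascade training parameters.

    ``f``: maximum per-stage false-positive rate; ``d``: minimum per-stage
    detection rate; ``F``: target global false-positive rate (training
    stops once the running product of stage rates reaches it);
    ``selection_mode``: ``"confidence"`` or ``"random"`` hard-negative
    selection after the first stage.
    """

    f: float = 0.5
    d: float = 1.0
    F: float = 0.05
    selection_mode: str = "confidence"
    max_stages: int = 25
    max_stumps_per_stage: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.f < 1.0):
            raise ValueError("f must be in (0, 1)")
        if not (0.0 < self.d <= 1.0):
            raise ValueError("d must be in (0, 1]")
        if not (0.0 < self.F < 1.0):
            raise ValueError("F must be in (0, 1)")
        if self.selection_mode not in ("confidence", "random"):
            raise ValueError("selection_mode must be 'confidence' or 'random'")


class NegativePool:
    """Mutable store of negative feature vectors with permanent deletion.

    Selection only ever draws from alive members; a deleted sample never
    reappears. Original insertion order is preserved for stable
    tie-breaking.
    """

    def __init__(self, X: np.ndarray):
        self.X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        self.alive = np.ones(len(self.X), dtype=bool)

    def __len__(self) -> int:
        return len(self.X)

    @property
    def n_alive(self) -> int:
        return int(self.alive.sum())

    def alive_indices(self) -> np.ndarray:
        return np.flatnonzero(self.alive)

    def alive_samples(self) -> np.ndarray:
        return self.X[self.alive]

    def delete(self, indices: np.ndarray) -> None:
        self.alive[np.asarray(indices, dtype=np.intp)] = False


@dataclass
class CascadeModel:
    """A trained cascade: ordered stages plus bookkeeping.

    ``kind`` is ``"hard"`` (staged cascade) or ``"soft"`` (one long stage
    with per-prefix rejection thresholds in ``soft_thresholds``).
    ``training_meta`` records the configuration and per-stage statistics
    (stump count ``n_i``, cumulative rates ``F_i``/``D_i``, stage rates,
    pool occupancy and selection mode).
    """

    stages: list[StageClassifier]
    kind: str = "hard"
    window_h: int = 0
    window_w: int = 0
    feature_config: dict = field(default_factory=dict)
    soft_thresholds: list[float] | None = None
    training_meta: dict = field(default_factory=dict)

    @property
    def n_stages(self) -> int:
        return len(self.stages)

    # -- classification ----------------------------------------------------

    def classify_batch(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Labels, stages passed and exit margins for each row of ``X``.

        ``exit_margin`` is the confidence at the stage where the sample
        exits: the rejecting stage for negatives, the final stage for
        accepted samples.
        """
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if self.kind == "soft":
            return self._classify_soft(X)
        n = X.shape[0]
        alive = np.ones(n, dtype=bool)
        passed = np.zeros(n, dtype=np.intp)
        margin = np.zeros(n)
        for stage in self.stages:
            idx = np.flatnonzero(alive)
            if idx.size == 0:
                break
            conf = stage.confidence(X[idx])
            margin[idx] = conf
            acc = conf >= 0
            passed[idx[acc]] += 1
            alive[idx[~acc]] = False
        return alive, passed, margin

    def _classify_soft(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        (stage,) = self.stages
        thresholds = self.soft_thresholds or []
        n = X.shape[0]
        alive = np.ones(n, dtype=bool)
        passed = np.zeros(n, dtype=np.intp)
        margin = np.zeros(n)
        partial = np.zeros(n)
        for t, stump in enumerate(stage.stumps):
            idx = np.flatnonzero(alive)
            if idx.size == 0:
                break
            partial[idx] += stump.alpha * stump.predict(X[idx])
            conf = partial[idx] - thresholds[t]
            margin[idx] = conf
            acc = conf >= 0
            passed[idx[acc]] += 1
            alive[idx[~acc]] = False
        return alive, passed, margin


def cascade_classify(m: CascadeModel, x: np.ndarray) -> tuple[int, int, float]:
    """Classify a single feature vector with early exit.

    Returns ``(label, stages_passed, exit_margin)`` with label +1/-1.
    Later stages are never evaluated once one rejects (short-circuit).
    """
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    if m.kind == "soft":
        acc, passed, margin = m._classify_soft(x)
        return (1 if acc[0] else -1), int(passed[0]), float(margin[0])
    passed = 0
    margin = 0.0
    for stage in m.stages:
        margin = float(stage.confidence(x)[0])
        if margin < 0:
            return -1, passed, margin
        passed += 1
    return 1, passed, margin


def evaluate_rates(
    m: CascadeModel, X_pos: np.ndarray, X_neg: np.ndarray
) -> tuple[float, float]:
    """(F, D): accepted fraction of negatives and of positives."""
    X_pos, X_neg = np.atleast_2d(X_pos), np.atleast_2d(X_neg)
    if X_pos.shape[0] == 0 or X_neg.shape[0] == 0:
        raise ValueError("both evaluation sets must be non-empty")
    acc_p, _, _ = m.classify_batch(X_pos)
    acc_n, _, _ = m.classify_batch(X_neg)
    return float(acc_n.mean()), float(acc_p.mean())


def filter_pool(m: CascadeModel, pool: NegativePool) -> NegativePool:
    """Delete pool members the cascade classifies negative (true negatives).

    Afterwards exactly the accumulated false positives remain alive.
    """
    idx = pool.alive_indices()
    if idx.size:
        acc, _, _ = m.classify_batch(pool.X[idx])
        pool.delete(idx[~acc])
    return pool


def select_informative(
    pool: NegativePool, m: CascadeModel, k: int
) -> tuple[np.ndarray, np.ndarray, bool]:
    """The ``k`` alive pool samples closest to the newest stage's boundary.

    Ranks alive members by the final stage's margin (all alive members are
    false positives, so margins are >= 0) and returns the smallest ``k``,
    ties broken by original pool order. Returns ``(samples, indices,
    shortage)`` where ``shortage`` flags a pool with fewer than ``k``
    alive members (all of them are returned).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    idx = pool.alive_indices()
    if idx.size == 0:
        return pool.X[:0], idx, True
    last = m.stages[-1]
    conf = last.confidence(pool.X[idx])
    order = np.argsort(conf, kind="stable")
    sel = idx[order[: min(k, idx.size)]]
    return pool.X[sel], sel, idx.size < k


def select_random(
    pool: NegativePool, k: int, rng: np.random.Generator | int
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Uniform without-replacement selection among alive pool members."""
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    idx = pool.alive_indices()
    if idx.size == 0:
        return pool.X[:0], idx, True
    take = min(k, idx.size)
    sel = np.sort(rng.choice(idx, size=take, replace=False))
    return pool.X[sel], sel, idx.size < k


def train_cascade(
    X_pos: np.ndarray,
    pool: NegativePool,
    cfg: TrainConfig,
    feature_config: dict | None = None,
    window: tuple[int, int] = (0, 0),
) -> CascadeModel:
    """Train a staged cascade with balanced, pool-selected negatives.

    Stage ``i`` starts empty and gains one stump per inner iteration until
    its false-positive rate on its own training negatives drops to ``f``
    (after lowering the stage threshold enough to keep the detection rate
    on the positives at ``d``). The running products ``F_i`` and ``D_i``
    of stage rates are the recorded global-rate estimates; the outer loop
    stops once ``F_i <= F``. Between stages the pool is filtered by the
    whole cascade and the next balanced negative set is selected
    (confidence ranking or uniformly at random; the first stage is always
    random). Stops early, with a flag in ``training_meta``, when the pool
    empties or ``max_stages`` is hit.
    """
    X_pos = np.atleast_2d(np.asarray(X_pos, dtype=np.float64))
    if len(X_pos) < 2:
        raise ValueError("need at least 2 positive samples")
    if pool.n_alive < len(X_pos):
        raise ValueError("pool must hold at least |P| negatives")
    rng = np.random.default_rng(cfg.seed)
    n_p = len(X_pos)
    model = CascadeModel(
        stages=[], kind="hard", window_h=window[0], window_w=window[1],
        feature_config=dict(feature_config or {}),
    )
    meta: dict = {
        "config": {
            "f": cfg.f, "d": cfg.d, "F": cfg.F,
            "selection_mode": cfg.selection_mode, "max_stages": cfg.max_stages,
            "max_stumps_per_stage": cfg.max_stumps_per_stage, "seed": cfg.seed,
        },
        "stages": [],
        "flags": [],
    }
    model.training_meta = meta

    # first stage: random selection (no confidence information exists yet)
    X_neg, _, shortage = select_random(pool, n_p, rng)
    selection_used = "random"
    F_glob, D_glob = 1.0, 1.0
    while F_glob > cfg.F and model.n_stages < cfg.max_stages:
        stage = StageClassifier()
        stage_f, stage_d = 1.0, 1.0
        capped = False
        X_stage = np.vstack([X_pos, X_neg])
        y_stage = np.concatenate([np.ones(len(X_pos)), -np.ones(len(X_neg))])
        fitter = StumpFitter(X_stage, y_stage)
        w = np.full(len(y_stage), 1.0 / len(y_stage))
        while stage_f > cfg.f:
            if len(stage.stumps) >= cfg.max_stumps_per_stage:
                capped = True
                meta["flags"].append("stump_cap_reached")
                break
            w = boost_round(stage, fitter, X_stage, y_stage, w)
            if w is None:  # no weak learner beats chance
                capped = True
                meta["flags"].append("no_weak_learner")
                break
            stage.stage_threshold = 0.0
            decrement_threshold(stage, X_pos, cfg.d)
            stage_d = float(np.mean(stage.score(X_pos) >= stage.stage_threshold))
            stage_f = float(np.mean(stage.score(X_neg) >= stage.stage_threshold))
        if not stage.stumps:
            break
        model.stages.append(stage)
        F_glob *= stage_f
        D_glob *= stage_d
        meta["stages"].append({
            "n_i": len(stage.stumps),
            "stage_fpr": stage_f,
            "stage_dr": stage_d,
            "F_i": F_glob,
            "D_i": D_glob,
            "selection": selection_used,
            "n_neg": int(len(X_neg)),
            "pool_alive_before": int(pool.n_alive),
            "capped": capped,
        })
        if F_glob <= cfg.F:
            break
        filter_pool(model, pool)
        if pool.n_alive == 0:
            meta["flags"].append("pool_exhausted")
            break
        if cfg.selection_mode == "confidence":
            X_neg, _, shortage = select_informative(pool, model, n_p)
            selection_used = "confidence"
        else:
            X_neg, _, shortage = select_random(pool, n_p, rng)
            selection_used = "random"
        if shortage:
            meta["flags"].append("pool_shortage")
    meta["final_F"] = F_glob
    meta["final_D"] = D_glob
    if F_glob > cfg.F:
        meta["flags"].append("target_F_not_reached")
    return model


def train_soft_cascade(
    X_pos: np.ndarray,
    X_neg: np.ndarray,
    T: int,
    rejection_quantile: float = 0.0,
    feature_config: dict | None = None,
    window: tuple[int, int] = (0, 0),
) -> CascadeModel:
    """One long boosted stage with per-prefix rejection thresholds.

    After each prefix of ``t`` stumps, the rejection threshold ``r_t`` is
    the ``rejection_quantile`` of the positive samples' partial scores
    (the lower empirical quantile, so quantile 0 keeps every training
    positive). Classification rejects as soon as a partial score falls
    below its prefix threshold.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    stage = adaboost_train(X_pos, X_neg, T)
    X_pos = np.atleast_2d(np.asarray(X_pos, dtype=np.float64))
    partial = np.zeros(len(X_pos))
    thresholds: list[float] = []
    for stump in stage.stumps:
        partial += stump.alpha * stump.predict(X_pos)
        thresholds.append(float(np.quantile(partial, rejection_quantile, method="lower")))
    if thresholds:
        stage.stage_threshold = thresholds[-1]
    return CascadeModel(
        stages=[stage], kind="soft", window_h=window[0], window_w=window[1],
        feature_config=dict(feature_config or {}), soft_thresholds=thresholds,
        training_meta={"config": {"T": T, "rejection_quantile": rejection_quantile},
                       "round_errors": list(stage.round_errors)},
    )


# -- serialization ---------------------------------------------------------


def save_model(m: CascadeModel, path) -> None:
    """Write a cascade as structured YAML text.

    Floats round-trip exactly (repr-based, >= 17 significant digits).
    """
    doc = {
        "format_version": FORMAT_VERSION,
        "kind": m.kind,
        "window": [int(m.window_h), int(m.window_w)],
        "feature_config": m.feature_config,
        "stages": [
            {
                "stage_threshold": float(s.stage_threshold),
                "stumps": [
                    {
                        "feature_index": int(st.feature_index),
                        "threshold": float(st.threshold),
                        "polarity": int(st.polarity),
                        "alpha": float(st.alpha),
                    }
                    for st in s.stumps
                ],
            }
            for s in m.stages
        ],
        "soft_thresholds": (
            None if m.soft_thresholds is None else [float(t) for t in m.soft_thresholds]
        ),
        "training_meta": m.training_meta,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_model(path) -> CascadeModel:
    """Read a cascade model file, validating schema and version."""
    try:
        with open(path) as fh:
            doc = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        raise ModelFormatError(f"cannot parse model file {path}: {exc}") from exc
    if not isinstance(doc, dict):
        raise ModelFormatError(f"model file {path} is not a mapping")
    version = doc.get("format_version")
    if version != FORMAT_VERSION:
        raise ModelFormatError(
            f"unsupported model format_version {version!r} (expected {FORMAT_VERSION})"
        )
    try:
        stages = [
            StageClassifier(
                stumps=[
                    DecisionStump(
                        feature_index=int(st["feature_index"]),
                        threshold=float(st["threshold"]),
                        polarity=int(st["polarity"]),
                        alpha=float(st["alpha"]),
                    )
                    for st in s["stumps"]
                ],
                stage_threshold=float(s["stage_threshold"]),
            )
            for s in doc["stages"]
        ]
        window = doc["window"]
        return CascadeModel(
            stages=stages,
            kind=doc["kind"],
            window_h=int(window[0]),
            window_w=int(window[1]),
            feature_config=doc.get("feature_config") or {},
            soft_thresholds=doc.get("soft_thresholds"),
            training_meta=doc.get("training_meta") or {},
        )
    except (KeyError, TypeError, IndexError) as exc:
        raise ModelFormatError(f"malformed model file {path}: missing/bad field {exc}") from exc
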