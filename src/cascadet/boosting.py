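"""Discrete AdaBoost stage classifiers built from decision stumps.

A decision stump thresholds one feature: it predicts +1 iff
``polarity * (x[feature_index] - threshold) > 0``. Stage classifiers are
weighted votes of stumps, ``score(x) = sum_t alpha_t * h_t(x)``, accepted
when the score reaches the stage threshold (initially 0, i.e. the sign of
the vote). The margin ``score - threshold`` is the stage's confidence — the
quantity the cascade's hard-negative selection ranks.

Stump fitting is exact: the weighted 0-1 error is minimised over every
feature, every midpoint threshold between consecutive distinct sorted
values (plus -inf/+inf sentinels) and both polarities, with deterministic
tie-breaking (smallest feature index, then smallest threshold, then
positive polarity).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

EPS_MIN = 1e-10  # floor for boosting round error when a stump is perfect


@dataclass(frozen=True)
class DecisionStump:
    feature_index: int
    threshold: float
    polarity: int
    alpha: float = 0.0

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Vector of +/-1 predictions for a (n, f) feature matrix."""
        X = np.atleast_2d(X)
        raw = self.polarity * (X[:, self.feature_index] - self.threshold)
        return np.where(raw > 0, 1, -1)


@dataclass
class StageClassifier:
    """Weighted-majority vote of decision stumps with an acceptance threshold."""

    stumps: list[DecisionStump] = field(default_factory=list)
    stage_threshold: float = 0.0
    round_errors: list[float] = field(default_factory=list)

    @property
    def n_features_min(self) -> int:
        return 1 + max((s.feature_index for s in self.stumps), default=-1)

    def score(self, X: np.ndarray) -> np.ndarray:
        """Ensemble scores ``sum_t alpha_t h_t(x)`` for each row of X."""
        X = np.atleast_2d(X)
        if X.shape[1] < self.n_features_min:
            raise ValueError(
                f"input has {X.shape[1]} features, stage needs >= {self.n_features_min}"
            )
        out = np.zeros(X.shape[0])
        for s in self.stumps:
            out += s.alpha * s.predict(X)
        return out

    def confidence(self, X: np.ndarray) -> np.ndarray:
        """Margin relative to the acceptance threshold (score - threshold)."""
        return self.score(X) - self.stage_threshold

    def decide(self, X: np.ndarray) -> np.ndarray:
        """Boolean acceptance: score >= stage_threshold."""
        return self.score(X) >= self.stage_threshold


class StumpFitter:
    """Exhaustive stump search with the per-feature sort precomputed.

    The sorted order of the training matrix never changes across boosting
    rounds — only the sample weights do — so caching it makes each round
    a weight gather plus cumulative sums.
    """

    def __init__(self, X: np.ndarray, y: np.ndarray):
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (n_samples, n_features)")
        self.y = np.asarray(y)
        self.n, self.f = X.shape
        self.order = np.argsort(X, axis=0, kind="stable")
        xs = np.take_along_axis(X, self.order, axis=0)
        # thresholds: -inf, midpoints between consecutive values, +inf;
        # interior splits are valid only between distinct values
        self.thr = np.empty((self.n + 1, self.f))
        self.thr[0], self.thr[-1] = -np.inf, np.inf
        self.thr[1:-1] = 0.5 * (xs[:-1] + xs[1:])
        self.invalid = np.zeros((self.n + 1, self.f), dtype=bool)
        self.invalid[1:-1] = xs[:-1] >= xs[1:]

    def fit(self, w: np.ndarray) -> tuple[DecisionStump, float]:
        y, f = self.y, self.f
        w = np.asarray(w, dtype=np.float64)
        if not (set(np.unique(y[w > 0])) == {-1, 1}):
            raise ValueError("both classes must be present with positive weight")
        wp = np.where(y > 0, w, 0.0)[self.order]  # positive weight, sorted per feature
        wn = np.where(y < 0, w, 0.0)[self.order]
        total_pos, total_neg = wp[:, 0].sum(), wn[:, 0].sum()

        # split after sorted position k (k = -1 .. n-1): rows <= k predicted
        # by the "below" side. err_plus: predict +1 above the threshold.
        cum_pos = np.vstack([np.zeros(f), np.cumsum(wp, axis=0)])
        cum_neg = np.vstack([np.zeros(f), np.cumsum(wn, axis=0)])
        err_plus = cum_pos + (total_neg - cum_neg)
        err_minus = (total_pos + total_neg) - err_plus
        err_plus = np.where(self.invalid, np.inf, err_plus)
        err_minus = np.where(self.invalid, np.inf, err_minus)

        best = np.inf
        pick: tuple[int, float, int] | None = None
        for polarity, err in ((1, err_plus), (-1, err_minus)):
            col_k = np.argmin(err, axis=0)  # first (smallest-threshold) minimum
            col_err = err[col_k, np.arange(f)]
            jstar = int(np.argmin(col_err))  # first (smallest) feature index
            e = float(col_err[jstar])
            cand = (jstar, float(self.thr[col_k[jstar], jstar]), polarity)
            if e < best - 1e-15 or (
                abs(e - best) <= 1e-15 and pick is not None and cand[:2] < pick[:2]
            ):
                best, pick = e, cand
        assert pick is not None
        return DecisionStump(pick[0], pick[1], pick[2]), best


def train_stump(
    X: np.ndarray, y: np.ndarray, w: np.ndarray | None = None
) -> tuple[DecisionStump, float]:
    """Exhaustively fit the minimum-weighted-error decision stump.

    The search covers every feature, every midpoint threshold between
    consecutive distinct sorted values (plus -inf/+inf sentinels) and both
    polarities. Returns the stump (alpha unset) and its weighted 0-1
    error. Raises ``ValueError`` when only one class is present with
    positive weight.
    """
    X = np.asarray(X, dtype=np.float64)
    n = X.shape[0] if X.ndim == 2 else 0
    w = np.full(n, 1.0 / n) if w is None else w
    return StumpFitter(X, y).fit(w)


def adaboost_train(
    X_pos: np.ndarray, X_neg: np.ndarray, n_rounds: int
) -> StageClassifier:
    """Discrete AdaBoost with decision stumps on +/-1 labels.

    Round error ``eps_t`` gives ``alpha_t = 0.5 ln((1-eps)/eps)`` (with
    ``eps`` floored at 1e-10 when a stump is perfect); weights get the
    multiplicative exponential update and are renormalised. Training stops
    early if no stump beats chance. The initial acceptance threshold is 0.
    """
    if n_rounds < 1:
        raise ValueError("n_rounds must be >= 1")
    X = np.vstack([X_pos, X_neg]).astype(np.float64)
    y = np.concatenate([np.ones(len(X_pos)), -np.ones(len(X_neg))])
    w = np.full(len(y), 1.0 / len(y))
    stage = StageClassifier()
    fitter = StumpFitter(X, y)
    for _ in range(n_rounds):
        w = boost_round(stage, fitter, X, y, w)
        if w is None:
            break
    return stage


def boost_round(
    stage: StageClassifier,
    fitter: StumpFitter,
    X: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
) -> np.ndarray | None:
    """One AdaBoost round: fit, weight, append a stump; update weights.

    Returns the renormalised weights, or ``None`` (stage unchanged) when
    no stump beats chance.
    """
    stump, eps = fitter.fit(w)
    if eps >= 0.5:
        return None
    eps_c = min(max(eps, EPS_MIN), 1.0 - EPS_MIN)
    alpha = 0.5 * np.log((1.0 - eps_c) / eps_c)
    stump = replace(stump, alpha=alpha)
    stage.stumps.append(stump)
    stage.round_errors.append(float(eps))
    w = w * np.exp(-alpha * y * stump.predict(X))
    return w / w.sum()


def grow_stage(stage: StageClassifier, X_pos: np.ndarray, X_neg: np.ndarray) -> None:
    """Add one boosting round to an existing stage, continuing its weights.

    Reconstructs the AdaBoost weight state implied by the current stumps
    (the exponential-loss weights of the current ensemble) and fits the
    next stump against it.
    """
    X = np.vstack([X_pos, X_neg]).astype(np.float64)
    y = np.concatenate([np.ones(len(X_pos)), -np.ones(len(X_neg))])
    margin = np.zeros(len(y))
    for s in stage.stumps:
        margin += s.alpha * s.predict(X)
    w = np.exp(-y * margin)
    boost_round(stage, StumpFitter(X, y), X, y, w / w.sum())


def decrement_threshold(
    stage: StageClassifier,
    X_pos: np.ndarray,
    d_target: float,
    step: float | None = None,
) -> StageClassifier:
    """Lower the stage threshold until the detection rate on ``X_pos``
    reaches ``d_target``.

    The threshold moves down on a fixed grid of decrements of size
    ``(max - min positive score)/256`` (configurable via ``step``); the
    detection rate is non-decreasing as the threshold falls, so the first
    grid point reaching the target is taken. Returns the stage (mutated).
    """
    if not (0.0 < d_target <= 1.0):
        raise ValueError("d_target must be in (0, 1]")
    scores = stage.score(X_pos)
    n = len(scores)

    def detection(th: float) -> float:
        return float(np.count_nonzero(scores >= th)) / n

    if detection(stage.stage_threshold) >= d_target:
        return stage
    if step is None:
        step = (scores.max() - scores.min()) / 256.0
    need = int(np.ceil(d_target * n))  # accept at least this many positives
    target_th = np.sort(scores)[n - need]
    if step <= 0:
        stage.stage_threshold = target_th
        return stage
    k = int(np.ceil((stage.stage_threshold - target_th) / step))
    th = stage.stage_threshold - max(k, 1) * step
    while detection(th) < d_target:  # guard against float-grid edge cases
        th -= step
    stage.stage_threshold = th
    return stage
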