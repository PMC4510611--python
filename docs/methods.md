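# Methods

This note documents the models, defaults and numerical choices behind
`cascadet`, and what the synthetic benchmark does and does not show.

## Cascade model and training loop

A cascade is an ordered list of stage classifiers; a sample is positive
iff every stage accepts it. Each stage is a discrete AdaBoost ensemble of
decision stumps: stump `t` predicts `+1` iff
`polarity · (x[j] − θ) > 0`, the stage score is `Σ αₜ hₜ(x)` with
`αₜ = ½ ln((1−εₜ)/εₜ)`, and the stage accepts when the score reaches the
stage threshold (initially 0). The margin `score − threshold` is the
stage's confidence.

Training (per stage, given positives `P` and a balanced negative set
`N`, `|N| = |P|`):

1. add one stump (AdaBoost round on the stage's own training sets);
2. reset the stage threshold to 0, then lower it on a fixed grid until
   the detection rate on `P` reaches `d` (default 1.0);
3. stop growing once the stage false-positive rate on `N` is ≤ `f`
   (default 0.5).

Global-rate bookkeeping multiplies per-stage rates: `F_i = F_{i−1} ·
(stage FPr)`, `D_i = D_{i−1} · (stage Dr)`, starting from `F_0 = D_0 = 1`
(the conventional initialisation; starting the recursion at zero would
make the loop conditions vacuous). The outer loop stops when
`F_i ≤ F` (default 0.05), the pool empties, or `max_stages` is reached.

Between stages, the pool of negatives is filtered by the *whole* cascade
(the full-cascade reading subsumes filtering by the newest stage alone);
survivors are exactly the accumulated false positives. The next `|N|`
negatives are either

* **confidence selection** — the survivors with the smallest margin at
  the newest stage, ties broken by original pool order. Samples at the
  boundary get a classifier output equivalent to random guessing, i.e.
  approximately independent of the current cascade's decision, which is
  the condition under which adding a stage trained on them keeps the
  stages independent and the product rule for global rates tight;
* **random selection** — uniform without replacement (the bootstrap
  baseline). The first stage always selects at random, since no
  confidence information exists yet.

Deleted pool members never return; there is no background re-scanning to
replenish the pool. If fewer than `|P|` survivors remain, all of them
are used and the run is flagged (`pool_shortage`).

### Interpreting the logged rates

Stage rates are measured on the stage's own balanced training sets — the
positives and the *selected hard negatives* (no validation split is
used). The product `F_i` is therefore an estimate, not the operating
false-positive rate on the full negative population: a stage tuned to
reject its hardest negatives can still pass easier false positives it
never saw, so the measured rate on a whole negative directory is
typically larger than the logged product (the worked example in the
README shows 0.215 measured vs 0.029 logged). The `eval` command reports
the operating point honestly; the logged `F_i` sequence is the training
contract (`F_i ≤ f · F_{i−1}` at every accepted stage).

### Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `f` | 0.5 | max per-stage FPr (on stage training negatives) |
| `d` | 1.0 | min per-stage Dr (on training positives) |
| `F` | 0.05 | target global FPr (stop condition; 0.02–0.2 typical) |
| `selection_mode` | `confidence` | hard-negative rule after stage 1 |
| `max_stages` | 25 | outer-loop safety cap |
| `max_stumps_per_stage` | 200 | inner-loop safety cap (flagged if hit) |
| threshold step | (max−min positive score)/256 | decrement grid for step 2 |
| `EPS_MIN` | 1e−10 | floor on round error when a stump is perfect (caps α) |

### Soft-cascade baseline

One long AdaBoost stage of `T` stumps; after each prefix `t` a rejection
threshold `r_t` is set to the lower empirical `rejection_quantile` of the
positive samples' partial scores (quantile 0 ⇒ every training positive
survives every prefix). Classification rejects at the first prefix whose
partial score falls below `r_t`. This per-prefix quantile calibration is
a deliberate simplification of full sample-weighted rejection-threshold
tuning; it is a baseline, not a tuned competitor.

## Features

**Haar-like.** Five prototypes (2-rectangle horizontal/vertical,
3-rectangle horizontal/vertical, 4-rectangle diagonal) at every admissible
position and scale; `stride`/`scale_step` coarsen the grid (defaults 1/1 =
exhaustive). Sign conventions: left−right, top−bottom, centre−outer,
main-diagonal−anti-diagonal; any consistent choice is absorbed by stump
polarity. Evaluation is exact integer arithmetic through the integral
image. No per-window variance normalisation is applied: the synthetic
data controls illumination, and normalisation would add a second
nonlinear path the stump thresholds cannot distinguish from the feature
itself.

**Texture.** Intensities are linearly quantized from [0, 256): 256 levels
for the histogram statistics, 32 levels for the GLCM (bounding the matrix
at 32×32). The GLCM offsets are chessboard displacements — 0°→(0,+d),
45°→(−d,+d), 90°→(−d,0), 135°→(−d,−d) — symmetric (both directions
accumulated) and normalised to sum 1 by default. Texture statistics are
computed on the whole window. Logarithms are natural; `0·log 0 := 0`.
Quartiles are intensity quantiles (smallest level with cumulative
probability ≥ 0.25/0.5/0.75). First-order entropy is `−Σ h log h ≥ 0`.

Two Haralick formula variants are exposed. `standard` (default) uses the
conventional definitions: correlation is normalised by standard
deviations, sum variance is centred on sum average, difference variance
is the central second moment of `p_{|i−j|}`, sum entropy carries its
minus sign, and the second information measure of correlation is
`sqrt(1 − exp(−2(HXY2 − HXY)))` clipped at 0. `paper` is a literal
transcription of a commonly printed variant of the table in which those
five statistics appear respectively with a variance denominator, a
leading minus and sum-entropy centring, a raw second moment, no minus,
and no square root. Both modes share the remaining 14 statistics and are
tested; degenerate denominators (zero variance or zero marginal entropy)
return 0 with a flag rather than NaN.

## Detection

Multi-scale sliding window over an image pyramid: the image is
repeatedly downscaled by `scale_factor` (default 1.25) and the cascade's
native window slides at `stride`; accepted windows map back to original
coordinates by multiplying by the scale. Downscaling the image (rather
than scaling Haar rectangles) works identically for both feature
families, since co-occurrence features have no rectangle-scaling
analogue. Greedy score-descending non-maximum suppression merges
detections above IoU 0.3 (configurable). Early rejection makes the mean
number of stages evaluated per background window much smaller than the
stage count.

## Evaluation

A hard cascade is a binary classifier, so its ROC is swept with the
scalar ranking score `stages_passed + logistic(exit margin)` — a strictly
monotone refinement of the lexicographic order (rejection depth, margin)
in which fully accepted samples outrank all rejected ones. ROC curves
use the standard threshold sweep (ties step diagonally); pAUC is the
trapezoidal area over FPr ∈ [0, fpr_max] (default 0.5, the random-
guessing error of a two-class problem), unnormalised, with the right
boundary linearly interpolated from the left so a vertical jump exactly
at `fpr_max` contributes nothing. `fpr_max = 1` recovers the full AUC
(equal to the normalised Mann-Whitney U statistic, which the tests
verify). Cross-validation is stratified k-fold (default k = 10) with
seeded shuffling; σ is the sample standard deviation (n−1) across folds,
the same estimator for every detector.

## Synthetic benchmark

`generate_patches` emulates patch-classification corpora: positives hold
one centred object (Gaussian blob, oriented bar, or annulus) with mild
position/shape jitter over a heterogeneous background (flat, ramp, or
smoothed-noise clutter whose spatial correlation makes co-occurrence
statistics informative); negatives are background only. Intensities are
8-bit scale; defaults are contrast 60, noise σ 20, clutter background,
16×16 windows. A single `overlap ∈ [0, 1]` knob scales the object
amplitude by `1 − overlap`: 0 is near-separable, 1 makes the two class
laws *identical* (the generator consumes the same random draws either
way, so exchangeability is exact, not approximate). The standard
benchmark has three tiers (easy/medium/hard = overlap 0/0.3/0.6), each
with 200 positives and a 2000-negative pool — the 10× imbalance of real
corpora — plus one 96×96 scene with three planted objects.

What it does not emulate: real image statistics (edges, part structure,
pose and illumination variation), correlated backgrounds across patches,
label noise, and corpus scale (thousands of samples per fold). Passing
the benchmark shows the training loop, selection rule and evaluation
machinery behave as specified and that informative selection helps on
controlled data; it does not certify performance on any real detection
task.

Problem sizes for the shipped experiments were chosen for single-CPU
desk-scale runs: 16×16 windows with a coarse Haar grid (stride 3,
scale-step 3 ⇒ 753 features), 10-fold CV, 10 generator seeds. At this
scale each CV fold tests only 20 positives, so the across-fold σ of pAUC
is dominated by fold-sampling noise (~0.04): mean pAUC separates the two
selection rules cleanly (confidence selection wins on every seed), and
mean σ is slightly smaller for confidence selection, but the per-seed σ
ordering is near a coin flip. Resolving per-seed σ differences of the
order reported on large corpora (σ ≈ 0.005–0.01) would need
thousand-sample folds.

## Numerical choices

* Stump search: thresholds at midpoints between consecutive distinct
  sorted feature values plus ±∞ sentinels; ties broken by smallest
  feature index, then smallest threshold, then positive polarity —
  deterministic and identical to the exhaustive oracle.
* The per-feature sort order is cached per stage (only weights change
  between boosting rounds), making a round a gather plus cumulative sums.
* Threshold decrement: closed-form jump to the first grid point meeting
  the detection target (equivalent to stepping, without the loop), with a
  float-edge guard.
* All stochastic behaviour flows through explicit seeded generators
  (`numpy.random.default_rng`); fixed seed ⇒ byte-identical datasets and
  models. Model files round-trip floats at full repr precision.
* Degenerate inputs: single-class training sets raise; a stage that finds
  no above-chance stump stops training with a flag; empty pools return
  empty selections with a flag.

## Known limitations

* No pool replenishment: once the false-positive pool is exhausted the
  cascade stops, possibly above the target F (flagged).
* Logged `F_i` is a training-set product estimate, not an operating rate
  (see above).
* Haar features are axis-aligned only (no tilted variants); texture
  features are single-channel.
* The GLCM diagonal displacement is chessboard, not Euclidean — at
  distance d the 45° offset is (−d, +d), which differs from libraries
  that round the Euclidean offset (skimage matches only at d = 1 on
  diagonals).
* The soft-cascade baseline calibrates rejection thresholds only by
  positive-score quantiles.
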