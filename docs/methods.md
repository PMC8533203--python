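# Methods

This note documents the models, conventions and numerical choices behind
`poincarehrv`, in the order the pipeline runs them.

## RR-series editing

An RR series is one row per beat: the interval (ms) ending at that beat and
a label in {normal, aberrant, artefact}.  Editing follows the standard
pre-Poincaré protocol:

* **Isolated ectopics** (a single non-normal beat flanked by normal beats)
  have their interval replaced by the mean of the two flanking intervals
  and are relabelled normal.  Replacement acts on one interval only; an
  alternative scheme would redistribute the ectopic's coupling interval and
  the compensatory pause over two intervals, but with a single per-beat
  interval column the one-interval rule is the only well-defined choice.
  Runs of two or more non-normal beats are never interpolated — they are
  excluded downstream.  Boundary ectopics cannot be interpolated and are
  left in place (counted in `meta`).
* **Pair construction.**  The interval carried by beat *i* spans beats
  *i−1 → i* and is usable only when both endpoint beats are normal, so any
  interval preceding or following a non-normal beat is dropped.  A couple
  (RR(n), RR(n+1)) is emitted only when both intervals are usable —
  time-closed couples only, no pair ever spans an excluded beat.  One
  consequence worth knowing: after an artefact, the first interval of the
  resumed rhythm is also dropped, so splitting a recording at an artefact
  and re-joining loses exactly one couple relative to processing the halves
  separately.

## Grid and 2D plot geometry

Both plots share one square grid.  **Pixel size defaults to 8 ms** — close
to the 7.8 ms RR quantisation of a 128 Hz Holter digitiser — with half-open
bins `[origin + c·w, origin + (c+1)·w)`.  All features are in ms-derived
units, so they rescale transparently if a different pixel size is chosen.
Foreground connectivity is 8 (configurable to 4).

Cleanup of the binary raster:

1. **Area opening** removes connected components with fewer than 4 pixels
   (salt-and-pepper from residual artefacts).  Implemented via
   `skimage.morphology.remove_small_objects`; the threshold is inclusive of
   components of exactly 4 pixels (kept).
2. **Hole filling** converts background regions not connected to the image
   border into foreground (`scipy.ndimage.binary_fill_holes`), using the
   connectivity complementary to the foreground's (4 when foreground is 8),
   the standard duality that keeps diagonal chains hole-tight.

The variability-extension curve scans the cleaned image column by column;
VE(column) is the **vertical extent** `(max_row − min_row + 1)·w`, i.e. a
width reading that spans residual interior gaps, not a count of foreground
pixels.  VE is computed on the opened+filled image by default (the fill
immediately precedes feature extraction); a switch (`ve_on_filled=False`)
computes it on the opened-only image instead.

Feature conventions where more than one definition is defensible:

* `L` is the **extent** between outermost occupied column edges, spanning
  internal gaps — a "length" should not shrink because a fan-shaped plot is
  gappy.  Column counting is therefore *not* used.
* Ties for the VE maximum resolve to the **lowest RR** column; RR\* is that
  column's bin center.
* `P = 100·(RR* − left edge of support)/L`, clamped to [0, 100].  For a
  single-column plot this gives the degenerate value 50%.
* `A` is the filled-foreground pixel count times `w²`, in ms².

## 3D plot, peaks and inertia

The occurrence histogram uses the same grid and the same label-filtered
pair stream; no morphological cleanup is applied to the counts (a flag can
mask bins that the 2D opening removed, off by default).

* **Peaks** are 8-connected equal-count plateaus that are regional maxima
  (strictly greater than every neighbour outside the plateau), counted once
  at their centroid, and kept when their height is **≥ half the global
  maximum** (inclusive).  The half-maximum default is where the peak count
  stabilises: lower thresholds inflate the count rapidly, higher ones
  suppress genuine secondary peaks.  The histogram is zero-padded before
  maximum detection so a plateau touching the array edge — including the
  degenerate fully-flat histogram — is still a maximum.  No smoothing is
  applied.
* `Dp` is the mean **perpendicular** distance |x−y|/√2 of peaks from the
  identity line; the plain |x−y| reading is available as a config switch.
* **Inertia radii** treat each occupied bin as a **unit point mass** at
  (x-center, y-center, count): the barycenter is the arithmetic mean of the
  N points and each radius is the RMS spread about it along one raw axis.
  Unit masses (rather than count weights) are the reading consistent with
  count-scale ρz magnitudes and with ρx ≈ ρy on near-symmetric plots; a
  count-weighted variant sits behind `weighted=True`.  Radii are taken
  along the raw RR(n)/RR(n+1) axes, not the rotated identity-line frame —
  the rotated frame would force ρx ≫ ρy on any elongated plot, which is not
  how these descriptors behave.

## Synthetic tachograms

The generator produces *fixtures with controllable morphology*, not a
physiological model.  One recording is

`RR(n) = trend(n) + σ(n)·AR1(n) + alternans(n)`,

with a circadian sinusoid plus a faster modulation as the trend (plus
piecewise cluster offsets for the "complex" pattern), AR(1) noise
(coefficient 0.8) scaled by `σ(n) = short_var·(1 + var_slope·(trend −
base)/base)` so the spread depends on the local RR (positive slope → comet,
≈0 → torpedo, strongly negative → fan), short-long alternation in a random
subset of segments (pulsus-alternans-like; it is what keeps the off-diagonal
structure and Dp from being identically degenerate), and isolated/run
ectopy at configurable rates with exact bookkeeping in `meta`.  Intervals
are floored at 200 ms.  Defaults describe a 24-h Holter recording:
100 000 beats around 850 ms.

The two-class cohort factory (`default_cohort_spec`, 138 low-risk vs 61
high-risk subjects) gives the high-risk class ~20–27% lower short-term
spread, circadian amplitude and spread-vs-RR slope — the direction and
relative size of the group differences reported for severe heart failure —
with between-subject parameter spreads chosen deliberately tight (a
homogeneous cohort without comorbidity heterogeneity).  Consequently the
synthetic classes separate more cleanly than real clinical groups: passing
end-to-end tests demonstrates that the pipeline detects effects of this
shape, not that real NYHA classes are this separable.  Other known gaps
from real data: histogram peaks stay close to the identity line (Dp near
zero; real 24-h plots show off-axis peaks tens of ms out), peak counts are
single-digit rather than in the tens, and trend dynamics are far smoother
than real circadian physiology.

## Statistics

* **Normality gate**: Lilliefors-corrected Kolmogorov–Smirnov (parameters
  estimated from the sample) on pooled within-group residuals; the plain
  KS-with-sample-moments variant is available by config.  A feature goes to
  one-way ANOVA iff its normality p > α (0.05), else Kruskal–Wallis; it
  never receives both.
* **Post-hoc** only after a significant omnibus test: Bonferroni-adjusted
  pairwise t-tests pooling the ANOVA MSE, or Dunn's rank test with tie
  correction and Bonferroni adjustment (written in-house; no installed
  package provides Dunn's test).
* **Logistic regression**: collinearity pruning removes, from each |r| >
  0.7 pair, the member with the weaker univariate label association
  (larger omnibus p; later column order breaks exact ties), deterministic
  by construction.  An explicit include-list can bypass pruning to fit a
  structurally fixed model.  Predictors are z-scored internally for the
  Newton solver (areas in ms² sit next to percentages) and coefficients are
  mapped back to per-unit odds ratios; if the Hessian goes singular under
  quasi-separation the fit falls back to BFGS, and complete single-feature
  separation is detected up front and reported as an error naming the
  feature.
* **Outlier screening** (provisional fit, flagged rows removed, one refit):
  a row is removed when its Cook's distance exceeds the classic absolute
  cutoff 1.0 or its unweighted centered covariate leverage exceeds
  2(k+1)/n.  Two deliberate choices here: leverage is computed from the
  *unweighted* predictor matrix because GLM-weighted leverage tends to zero
  exactly where a covariate outlier is most extreme (fit weight p(1−p)→0),
  hiding it; and the Cook's cutoff is absolute rather than n-relative
  because an n-relative rule (e.g. 4/n) deletes several percent of
  perfectly clean observations and measurably biases the odds ratios
  upward (simulated 95% CI coverage collapses from ≈0.99 to ≈0.6).
  Trimming on covariate leverage only conditions on x and leaves the
  fitted model unbiased.
* **Events-per-variable guard**: the smallest class (after outlier
  removal) divided by the number of predictors must exceed 10, else the
  fit is refused with a diagnostic.

## Classification

Stratified 80/20 hold-out, then per algorithm a wrapper that scores every
candidate feature subset by mean accuracy over one fixed, seeded,
stratified 10-fold partition of the training set (identical folds for all
subsets).  The default search is exhaustive over all 2⁹−1 = 511 non-empty
subsets; ties resolve to the smaller subset, then lexicographic feature
order, guaranteed by evaluating in that order and keeping strict
improvements only.  Greedy forward selection is available
(`wrapper="greedy"`) and is what the heavy multi-seed end-to-end tests use;
with 20 replicates of the full pipeline the exhaustive AdaBoost wrapper
(5 110 boosted fits per replicate) would be disproportionate to what the
test demonstrates, and on these cohorts greedy reaches the same qualitative
result.  Test rows touch nothing before the final evaluation — a canary
test perturbs them and asserts the selected subset is unchanged.

Classifiers and hyperparameters (none are given by the problem definition;
all are logged in the run summary): AdaBoost over depth-3 decision trees,
50 rounds, learning rate 1.0 — implemented as a thin SAMME loop over
`sklearn` trees (`ml._BoostedTrees`) whose per-fit overhead is ~3× lower
than the stock estimator wrapper, which matters inside a 511-subset × 
10-fold search; its predictions are cross-checked against
`sklearn.ensemble.AdaBoostClassifier` in the test suite.  kNN uses k = 5
(odd, tie-free), Euclidean distance, features standardised with training
statistics only.  Naive Bayes is Gaussian.  AUCROC is computed from
continuous scores (vote margins / probabilities), high risk positive.

## Problem sizes used by the test suite

Unit tests run on small crafted rasters and short series.  The oracle suite
checks each geometry operator against an independently coded brute-force
implementation on 200 random instances up to 50×50.  Statistical
calibration uses 500 null replicates (group sizes 22/116/61) for the
type-I error and 200 replicates at n = 500 for odds-ratio CI coverage.
The end-to-end check runs 20 seeded 138/61 cohorts at 100 000 beats per
subject with the greedy wrapper.  The acceptance script runs one cohort at
the same scale with the full exhaustive wrapper.

## Known limitations

* The VE "width" and `P` reference-point conventions, the tie-break at the
  VE maximum, and the unit-mass inertia model are choices among defensible
  readings; all are switchable, and comparisons across studies should fix
  them explicitly.
* The synthetic cohort is a calibration fixture: effect directions and
  relative sizes are realistic, between-subject spread is not.
* Wald CIs from quasi-separated logistic fits can be effectively unbounded
  (reported as `inf`); an exact or penalised-likelihood method would be
  needed for honest inference in that regime.
* The editing pipeline assumes upstream beat labels are trustworthy; no
  attempt is made to re-detect mislabelled beats.
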