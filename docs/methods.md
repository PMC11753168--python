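# Methods

This note records the model, the numerical choices and the known
limitations of `actimotif`, at the level of detail a user needs to
judge what a passing test suite does and does not establish.

## Elastic distance

Curves are sampled on uniform grids over [0, 1] with at least 8 points.
The SRVF q = f′/√|f′| uses second-order centered finite differences
(one-sided second-order at the boundaries); where |f′| < 1e-8 the
transform is set to 0, its limiting value for vanishing velocity. The
transform has no free constructor — `SRVFCurve` objects only come out
of `srvf_transform` — so downstream code can rely on that convention.

The optimal warp minimizing ‖q₁ − (q₂∘γ)√γ̇‖ is found in two stages:

1. **Global lattice search.** Dynamic programming over monotone paths
   on the n×n sample lattice with segment slopes restricted to coprime
   ratios p/q, p, q ≤ 7 (the unit-slope step is tried first so exact
   ties resolve toward the identity). Segment costs use a midpoint rule
   refined along the steeper axis. Degenerate pairs whose SRVFs are
   both numerically zero return the identity warp.
2. **Continuous refinement.** The lattice quantizes γ̇ to a coarse set
   of rationals, and the objective depends on √γ̇, so the staircase
   dominates the residual. A local pass therefore minimizes the same
   midpoint objective over all monotone warps: increments
   e_c = γ_{c+1} − γ_c are parameterized by a softmax (monotonicity and
   the boundary conditions hold by construction) and optimized by
   Armijo-backtracking gradient descent with an analytic gradient
   (numba-compiled, ≤ 600 iterations). On a 201-point grid this drives
   the amplitude residual of a pure-warp pair from ~0.1 to ~1e-3.

The amplitude distance is evaluated with per-cell constant slopes and
midpoint quadrature; the phase integral ∫√γ̇ is exact for the
piecewise-linear warp (Σ√(Δγ·Δt)), clamped into [−1, 1] before the
arccos. Warping a curve (`warp_curve`) interpolates with a cubic
spline, which keeps exact-composition identities (e.g. (t²)∘√t = t)
below 1e-6.

**Order convention and symmetry.** Distances are computed once, in the
order given (the second curve is warped onto the first); symmetry is a
verified tolerance, not an enforced construction. For curve pairs that
share a common underlying shape — the regime in which segments are
compared to motif centers — the forward and reverse distances agree to
~1e-2 in median. For strongly dissimilar pairs the discrete objective
can under-count cost in very steep warp cells (pinching, a known
degeneracy of the unconstrained SRVF infimum), and the two orders can
then disagree by ~10%. All package internals use a fixed argument
order, so results are well-defined and reproducible regardless.

Default weights split equally across all phase/amplitude terms
(w_{p,h} = w_{a,h} = 1/(2H)); any nonnegative weights summing to one
are accepted.

## Motif clustering

Initial centers are K distinct segments drawn without replacement under
the given seed. Assignment breaks ties toward the lower cluster index;
the center update is the literal pointwise mean of the raw (unaligned)
member curves. Because the update is not the Fréchet mean under the
elastic metric, monotone descent of the within-cluster objective is not
guaranteed; the per-iteration objective is recorded but descent is not
asserted. Iteration stops when the label-change fraction is ≤ tol
(default 0) or after max_iter (default 50). Empty clusters are reseeded
with the segment farthest from the empty cluster's previous center.

Random-segment initialization is seed-sensitive: when several initial
centers land in the (abundant) sleep-like segment mass, distinct active
motifs can merge and the plain-mean update cannot split them.
`fit_motifs(..., n_restarts=r)` reruns the fit from restart seeds
derived deterministically from the main seed and keeps the run with the
smallest final objective; the default is a single start.

Segment SRVFs are cached across iterations; center SRVFs are recomputed
each iteration (centers change, segments do not). Diagnostics: the
within/between ratio divides total segment-to-center distance by total
center-to-center distance; the silhouette uses the full pairwise
elastic-distance matrix (computed once and shared across a K grid in
`select_k`). For K = 1 both diagnostics are NaN. `select_k` reports the
table and leaves the choice of K to the user, matching multi-criteria
practice (ratio elbow, silhouette peak, downstream performance).

## Daily means, FPCA and scores

The daily cluster mean is the pointwise average of the day's member
segments, and exactly the zero function when the day has no segments in
that cluster; zero-function days are *included* when fitting FPCA,
since they are defined values, not missing data. FPCA eigendecomposes
the sample covariance about the cluster mean under trapezoidal
quadrature; eigenfunctions are orthonormal under that quadrature, with
signs fixed so ⟨φ_p, 1⟩ ≥ 0 (fallback: largest-magnitude coordinate
positive). The truncation order is the smallest P reaching the target
explained fraction (default 0.80) or a fixed P; if fewer informative
components exist the order is reduced with a warning, and a family of
identical curves yields P = 0 with all scores zero. Scores are
quadrature inner products of the centered daily means with the
eigenfunctions. For triaxial data, clustering and FPCA can be run per
axis (giving K·P·H score columns) or jointly through the multi-axis
metric; both modes use the same functions, applied per axis slice.

## Association model

Day rows are treated as independent observations. The lasso penalty is
chosen by 5-fold cross-validation whose folds never split a subject
(fold assignment is a seeded permutation of subjects, round-robin).
Both validation deviance and misclassification rate are tracked, each
yielding a one-standard-error choice — the strongest penalty within one
SE of that loss's best mean — and the stronger of the two penalties is
used. The deviance curve rises sharply on null data (keeping chance
correlations out), while the error curve is the sharper guide when real
effects exist; taking the more conservative choice gives empty supports
on ~90% of null datasets while recovering 3/3 planted |β| = 0.5 effects
with a median of zero false positives at n = 600 day-rows.

The selected score columns, plus all covariates, are refit by plain
logistic regression (statsmodels) to report odds ratios, 95% Wald
intervals and Wald p-values. Binary covariates that perfectly separate
the outcome are detected and dropped up front; covariates whose refit
coefficients diverge (quasi-separation) are dropped iteratively with a
warning, mirroring how a covariate that perfectly splits the groups
must be excluded for the MLE to exist. If the scores themselves
separate the data, a capped-iteration IRLS fit is reported (with
correspondingly huge intervals) rather than failing.

## Classification protocol

Leave-one-subject-out: all of a subject's days are held out together;
the subject-level call is the majority vote of the daily predictions,
with even-split ties resolved by the mean predicted case probability
≥ 0.5. Metrics (accuracy, sensitivity, specificity) are computed at the
subject level from stored confusion counts. The five classifiers run
with library defaults frozen in `CLASSIFIER_CONFIG` (random forest: 500
trees); the SVM sees standardized features, since margin methods are
not scale-invariant, while the other classifiers see raw scores.

A property worth knowing: on data with *no* signal, LOSO is
systematically pessimistic — the held-out subject's class is always the
training minority in a balanced cohort, and majority voting amplifies
the resulting bias, pushing null accuracy below 0.5 as the number of
voted days grows. This is a property of the protocol, not a bug; the
chance-level test uses 3 voted days, where the bias is small.

## Preprocessing

Days run local midnight to midnight using the file's own dates; a
retained day has exactly 1,440 nonnegative non-missing minutes per axis
(duplicate minutes keep the first occurrence; malformed or negative
rows are rejected and counted). Counts are divided by 1,000 by default.
Sub-minute streams are aggregated by the per-minute median (midpoint
convention for even counts). Optional smoothing is a P-spline: 50 cubic
B-splines per day with a second-difference coefficient penalty
(λ = 10); constants are in the penalty null space, so flat days pass
through unchanged, and output is clipped at zero. Note that 50 bases
over a day is knot spacing ≈ 30 min — it suppresses minute-level noise
but also attenuates sub-window shape, so clustering on unsmoothed
segments is often preferable when windows are short. Windows are
anchored at minute 0, non-overlapping, and each rescaled to [0, 1].

## Synthetic data generator

The generator emulates: 1,440 samples/day per axis; nonnegative scaled
counts; recurring window-length motifs (sleep-like flat-low, flat-high,
single bump, double bump, ramp) drawn per window from block-specific
probabilities over four 6-hour blocks (the sleep-like template
dominates 00:00–05:59); random boundary-preserving warps built from
Dirichlet-style positive increments and shrunk so the maximum deviation
from identity equals the configured intensity (default 0.1);
multiplicative amplitude jitter (sd 0.1); a case-group amplitude
multiplier (default 0.7) on active templates; and additive noise
(sd 0.02 in scaled-count units — the scale of minute-to-minute
variation left after dividing counts by 1,000; larger values drown the
sleep template, whose whole amplitude is 0.05). Emitted per-minute
files are valid preprocessing inputs (values ×1,000, float precision,
so the degenerate no-noise configuration round-trips template values
exactly).

What it does **not** emulate: device non-wear, missingness patterns,
autocorrelated within-window noise, between-subject template shape
heterogeneity, or realistic count marginal distributions. Passing
recovery tests therefore show the algorithms work when their modeling
assumptions hold, not that real cohorts are this clean.

Score-table generators (`generate_biomarker_table`,
`generate_classification_table`) plant logistic effects on named score
columns, with day-level or subject-level outcomes, for testing the
model layer in isolation.

## Pipeline and determinism

One config drives simulate → preprocess → cluster → biomarkers →
models; unknown config keys fail before any stage runs. All randomness
derives from one root seed through `numpy` SeedSequence spawning (one
child per stage, reduced below 2³¹). Every run writes exactly one
manifest with parameters, derived seeds and SHA-256 digests of all
outputs; floats are written via fixed formats so rerunning an identical
config reproduces identical digests. A non-empty output directory is
refused without `force`.

## Problem sizes in the test suite

The suite exercises: 201-point grids for elastic-distance oracles and
50 seeded warp pairs; 40–60 segments (30 points each) over 10 seeds for
motif recovery and a K grid of 2–6 for selection; 200 curves for FPCA
recovery; 60 subjects × 10 days (12 score columns) over 20 seeds for
lasso selection; 10–20 subjects for the classification protocol; and a
2×4-subject, 3-day cohort for the digest-checked golden pipeline run.
These sizes make every property measurable while keeping the full suite
in the minutes range on one CPU.

## Known limitations

- The discrete amplitude distance is order-dependent for strongly
  dissimilar curves (pinching; see above). Within-package uses fix the
  order.
- The plain-mean center update is faithful to the clustering algorithm
  as specified but is not a Fréchet mean; the objective can plateau or
  oscillate, hence the label-stability stopping rule.
- Smoothing at the default basis size trades sub-window detail for
  noise suppression; tune `basis_size` to the window length.
- Wald inference after lasso selection ignores selection uncertainty;
  p-values are conditional on the selected support, as in standard
  refit practice.
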