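# actimotif

Elastic distance-based motif clustering and digital-biomarker extraction
for free-living physical-activity (actigraphy) data.

Wearable devices record per-minute activity counts with no labels for
what the wearer was doing. `actimotif` finds recurring short-window
activity patterns ("motifs") in such data, turns them into quantitative
per-day features, and links those features to health outcomes. It is
aimed at biostatisticians and epidemiologists working with
minute-resolution accelerometry cohorts (single-axis activity counts or
minute-level triaxial summaries).

## The method

**Elastic shape analysis.** An activity segment is a curve
f : [0, 1] → ℝ, represented by its square-root velocity function (SRVF)
q(t) = f′(t)/√|f′(t)|. Warping f by a monotone, boundary-preserving
γ maps q to (q∘γ)·√γ̇, so after minimizing over γ (dynamic programming
over lattice warps, followed by a continuous refinement of the warp
increments) the discrepancy between two curves separates into

- amplitude distance  d_amp(f₁, f₂) = ‖q₁ − (q₂∘γ*)√γ̇*‖ — the
  shape/intensity difference net of timing, and
- phase distance  d_phs(f₁, f₂) = arccos ∫₀¹ √γ̇*(t) dt ∈ [0, π/2] —
  the timing difference.

The working metric is the convex combination
d = Σ_h [w_{p,h}·d_phs + w_{a,h}·d_amp] over axes h, with
Σ_h (w_{p,h} + w_{a,h}) = 1.

**Motif clustering.** Days are cut into fixed non-overlapping windows
(15/30/60 min, each rescaled to [0, 1]); K-means alternates between
assigning every segment to the elastically nearest center and updating
each center as the pointwise mean of its raw member curves. Cluster
number is guided by the within/between variation ratio and the mean
silhouette width on the pairwise elastic-distance matrix.

**Digital biomarkers.** For subject i, day d and motif k, the daily
cluster mean A_id^(k)(t) averages that day's member segments (zero
function if none). Functional PCA within each motif yields mean μ^(k),
eigenfunctions φ_p^(k) and scores ξ_idp^(k) = ⟨A_id^(k) − μ^(k), φ_p^(k)⟩ —
the biomarkers.

**Models.** Association: logistic regression of the outcome on all
scores plus covariates, lasso-penalized with the penalty chosen by
subject-grouped cross-validation (one-standard-error rule), then an
unpenalized refit for odds ratios, 95% CIs and p-values.
Classification: leave-one-subject-out cross-validation with majority
voting of daily predictions, for five classifiers (naive Bayes, SVM,
lasso logistic regression, decision tree, random forest).

A seeded synthetic-actigraphy generator with planted motif templates,
random phase warps, amplitude jitter, circadian placement and a
case/control amplitude effect makes every stage testable offline.

## Worked example

`examples/01_elastic_distances.py` separates timing from shape for a
pair of curves that differ only by the time warp γ(t) = t²:

```
amplitude distance : 0.0037   (0 for a pure time warp)
phase distance     : 0.3366   (analytic: arccos(2*sqrt(2)/3) = 0.3398)
t vs 2t amplitude  : 0.4142   (analytic: sqrt(2)-1 = 0.4142)
t vs 2t phase      : 0.0000   (identity warp is optimal)
```

The warped pair shows almost pure phase discrepancy (0.3366 against the
analytic 0.3398) and essentially no amplitude discrepancy; the pair
t ↦ t vs t ↦ 2t shows the opposite — all amplitude (√2 − 1), no phase.

`examples/02_motif_clustering.py` continues the story on a synthetic
cohort: 192 half-hour segments built from three planted templates are
clustered with K = 3 and recovered exactly:

```
4 days -> 192 segments of 30 min
converged in 5 iterations; cluster sizes [58, 55, 79]
ARI vs planted templates : 1.000   (1.0 = exact recovery)
mean silhouette width    : 0.597
```

The remaining examples walk through FPCA biomarkers, association and
LOSO classification, and the fully seeded end-to-end pipeline. A thin
CLI mirrors the pipeline stages
(`actimotif simulate|preprocess|cluster|biomarkers|run`).

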