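# Methods

This note documents the models, conventions and numerical choices
behind `enmrisk`, in the order the pipeline applies them, together with
what the synthetic benchmark does and does not demonstrate.

## Presence-background maximum-entropy model

The niche model is the regularized Gibbs formulation of
presence-background modelling: a density `raw(x) = exp(λ·f(x))/Z` over
background cells, with `λ` minimizing

    −(1/m) Σᵢ λ·f(xᵢ) + log Z(λ) + Σⱼ βⱼ|λⱼ|.

This objective shares its optimum with the classical sequential-update
algorithm; we solve it as a smooth bound-constrained problem by
splitting `λ = λ⁺ − λ⁻` (both ≥ 0) and running L-BFGS-B with analytic
gradients (`ftol` 1e-14, projected-gradient tolerance 1e-6, default cap
2000 iterations). Coefficients with |λ| < 1e-5 after convergence are
set to exact zero; the count of nonzero coefficients is the `k` used by
AICc. Unit tests check the solver against derivative-free and
grid-search minimizers of the same objective (agreement to |Δλ| ≤ 1e-2)
and the empirical lasso-path property that doubling the regularization
multiplier never increases the number of nonzero coefficients.

**Features.** Linear, quadratic and pairwise-product features are built
from the raw predictors; threshold features are step functions at 10
evenly spaced interior knots per variable; hinge features are forward
and reverse ramps anchored at 11 evenly spaced knots (10 of each
direction per variable). Every feature column is min-max rescaled to
[0, 1] with constants from the background sample, so the per-class
penalty constants are comparable. Penalties are
`βⱼ = RM · c_class · sdⱼ(presence features) / √m`, with
`c_class` = 1.0 for linear/quadratic/product, 0.5 for hinge, 2.0 for
threshold — a deliberate simplification of the published interpolation
tables that preserves their ordering (hinge penalized least, threshold
most). A feature constant across presences gets sd replaced by 1 to
avoid a vanishing penalty.

**Background.** All valid cells of the calibration area when there are
at most 50,000; otherwise a seeded uniform sample of 10,000. Raw output
therefore sums to exactly 1 over this set (tested to ±1e-6).

**Transfer.** On projection, predictor values are clamped to the
background range seen at fit time (clamping on, as is conventional);
extrapolation control beyond that is handled by cropping projections to
the calibration area rather than by extrapolation masks.

**Logistic output.** `τ·e^H·raw / ((1−τ) + τ·e^H·raw)` with prevalence
τ = 0.5 and `H` the Shannon entropy of the fitted background
distribution, which reduces to `e^H·raw/(1+e^H·raw)`: a model with no
information (all coefficients zero) outputs exactly 0.5 everywhere, and
the transform is strictly rank-preserving with respect to raw output.

## Candidate calibration and selection

The candidate grid crosses the regularization multipliers
(0.1, 0.5, 1, 2) with all 31 non-empty subsets of `{l,q,p,t,h}` — 124
configurations, enumerated in a stable order (subset size, class order,
multipliers innermost).

**Partial ROC.** The evaluation region is fixed per dataset as the
threshold range over which the *full* test set keeps sensitivity
≥ 1−E (its upper edge is the E-omission suitability value of the test
presences); it is sampled at 100 evenly spaced thresholds. Each of the
bootstrap iterations resamples ⌈n/2⌉ test presences with replacement
and integrates its sensitivity-vs-proportion-of-area curve over that
region (trapezoid), divided by the area under the null diagonal on the
same region; p is the fraction of iterations with AUC ratio ≤ 1.
Fixing the region from the full test set is a deliberate choice: if the
region is re-selected from each resample's own noisy sensitivity curve,
the selection conditions on upward noise and the null rejection rate
inflates to ~11 %; with the fixed region the test is calibrated (mean
null ratio ≈ 1.003, rejection 2–10 % at nominal 5 % across seeds, 200
simulated null datasets with 162 test presences and 500 iterations).

**Omission rate.** Fraction of test presences strictly below a
threshold taken from the training suitabilities at E = 5 %. Here the
threshold is the ⌊E·n⌋-th smallest training suitability rather than
the (⌊E·n⌋+1)-th used for binarization: with the latter, the expected
omission of new presences is (⌊E·n⌋+1)/(n+1), which exceeds E for
almost every n, so a perfectly calibrated model would fail an
"omission ≤ E" cut more often than not and whole well-specified
candidate families get eliminated together on a third of random
landscapes. The ⌊E·n⌋-th order statistic is the largest threshold whose
expected novel-point omission stays ≤ E, making the filter consistent
with its own cut.

**Selection cascade.** Significance (p ≤ 0.05) → omission ≤ 5 % →
ΔAICc ≤ 2, with ΔAICc recomputed among the survivors of the first two
stages. AICc uses the raw densities renormalized over the landscape at
the presence points, `k` = nonzero coefficients, and is invalid when
k ≥ n−1 or any presence has zero density. If a stage eliminates every
candidate it is reported and skipped (strict mode raises instead) —
at very small sample sizes the omission stage is often unattainable
because omission is quantized at 1/n_test. Ties among selected
candidates resolve to the lowest AICc, then fewest parameters.

**Final model.** The selected configuration is refit on the complete
occurrence set through 5 bootstrap resamples; the per-cell mean of the
logistic surfaces is the final prediction, and the replicates are kept
for spread diagnostics.

## Binary maps, range change, risk

* **Binarization:** threshold = (⌊E·n⌋+1)-th smallest training-presence
  suitability at E = 20 % (at most ⌊E·n⌋ training presences fall below;
  E = 0 reduces to the minimum presence threshold); presence is
  inclusive (≥). Future projections are binarized with the same
  training threshold and cropped to the calibration area.
* **Change accounting:** per-cell classification into stable-absent /
  gained / lost / maintained; summary percentages are taken over the
  union of current and future presence, so they sum to exactly 100, and
  the overlap index O = |f∩p|/|f∪p| equals the maintained fraction.
  (The union denominator is the only convention under which the three
  percentages can sum to 100; O is computed cell-exactly.)
* **Threat overlays:** human-footprint overlap uses a strict cut
  (> 10); protected-area coverage rasterizes the dissolved polygon
  union by cell-center coverage (overlapping polygons counted once);
  the congener contact zone is the intersection of both species' binary
  ranges in the same scenario, reported relative to the focal range.
* **Risk maps:** per scenario, a loss cell is current-present ∧
  future-absent and a contact cell lies in both species' future ranges;
  consistency layers count scenarios per cell. With weights 0.7/0.3 and
  scale 10 the weighted sum is exactly the integer `7a + 3b`, so with
  4 scenarios the attainable positive values run 3…40 — matching the
  published construction's printed minimum and maximum. Zero-risk cells
  are maintained in all scenarios with contact in none; by construction
  they have a = b = 0 and risk 0 (validated at construction time).
  Categories: low 3–14, moderate 15–28, high ≥ 29; proportions are
  reported over at-risk cells with zero-risk kept separate.

## Preprocessing

Exact-duplicate removal on (species, x, y); greedy spatial thinning in
a seed-shuffled scan order, which guarantees the minimum-distance
constraint and inclusion-maximality (not global maximum cardinality)
and is idempotent; distances are Euclidean in map units (haversine
available for geographic coordinates). The train/test split is a seeded
permutation with |train| = round(fraction·n) and an environmental
coverage report (per variable, the share of the full min–max range
spanned by the training subset). The correlation filter computes
Pearson correlations over the background cells of the calibration area
and repeatedly resolves the strongest pair with |r| ≥ 0.8 by dropping
the lower-ranked variable (rank = single-variable jackknife gain, i.e.
the regularized training gain of a one-variable model); constant
variables are dropped up front with a warning, and the audit trail
records every drop with its partner and |r|.

## Synthetic landscapes

The generator trades realism for recoverable truth:

* predictors are Gaussian-filtered white noise (kernel sd =
  `corr_length` cells) plus a planar gradient in a seeded random
  direction (relative weight 0.5), standardized to mean 0, sd 1 — not
  bioclim look-alikes;
* the virtual species has parametric (Gaussian or logistic) response
  curves combined by product or geometric mean, so true suitability is
  analytic; the congener is derived by widening the breadths (×2) and
  shifting the optima (+1 sd), guaranteeing a partial contact zone;
* scenarios apply per-variable trends
  (`mult·x + add + gradient·y_norm + noise`) to the first predictor —
  a severity ladder (add 0.2/0.4/0.6/0.9 with matching poleward
  gradients) standing in for four emissions pathways; a zero shift is
  an exact identity;
* occurrences are drawn with probability ∝ suitability × optional bias,
  at cell centers with sub-cell jitter;
* the human-footprint surface is smoothed low-level noise plus
  Gaussian-shaped hotspots, clipped to [0, 50]; protected areas are
  random rectangles (3–8 cells a side) clipped to the extent.

Coordinates are planar map units on a square grid; no geodesy. A
row-weighted area option exists for geographic grids but defaults off.

What passing tests show: the estimator recovers a known smooth niche
(selected-model Spearman ρ ≥ 0.9 against truth on a 100×100 landscape
with 300 presences), the evaluation statistics are calibrated, and all
accounting identities hold exactly. What they do not show: robustness
to sampling bias, spatially structured detection error, predictor
collinearity regimes unlike the simulated ones, or geodesic effects —
real-data behaviour can differ in all of these.

## Pipeline, determinism, problem sizes

One pipeline seed drives everything; each stage derives a sub-seed by
SHA-256 hashing of `(seed, stage name)`, so reruns reproduce every
artifact bit-for-bit and individual stages can be regenerated from the
configuration alone. The default demonstration configuration (50×50
grid, 4 predictors, 150 presences, 4 scenarios, full 124-candidate
grid) runs in well under a minute on one CPU; the recovery benchmark
(100×100, 300 presences, RM grid × {l,q}) and the 200-dataset null
calibration of the partial-ROC test each run in seconds — sizes chosen
as the package's standard desk-scale benchmarks. The final-model
recovery benchmark restricts the candidate feature space to {l,q}
because that is the package's standard recovery benchmark
specification; threshold-feature models produce step-shaped surfaces
whose tied ranks depress Spearman correlations against a smooth truth
irrespective of fit quality.

## Known limitations

* Maxent penalty constants are simplified class multipliers, not the
  published interpolation tables; coefficient values differ from the
  Java implementation while the optimum structure is preserved.
* Selection near the omission cut remains stochastic: omission is
  quantized at 1/n_test and overfitting inflates training thresholds,
  so on some random landscapes every flexible candidate family fails
  the 5 % cut together and a simpler family is selected with visibly
  worse truth recovery.
* The congener's model configuration in the pipeline is fixed
  (linear+quadratic, RM 1) rather than independently calibrated — one
  calibration grid per run keeps the demo desk-scale.
* No geodesic reprojection or resampling: all rasters in a run must
  share one grid.
* Risk-layer encoding assumes scenario-consistency counts rescaled by
  10; if upstream layers encoded more than consistency (e.g. loss
  magnitude), the weighted sum would need re-deriving. Weights, scale
  and category bounds are configuration-exposed.
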