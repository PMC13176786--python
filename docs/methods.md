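# Methods

## The model

`wspfit` models transcript counts observed along a single bounded spatial
axis.  The axis (a laminar depth, a lobule radius, any functionally meaningful
1-D coordinate) is discretized into bins `0 .. n_bins - 1` with upper bound
`b_p = n_bins`.  For each gene `g` and cell type `c`, the log-linked kernel
rate is a sum of logistic transitions,

    log_e(lambda + 1) = Psi_d(x; r, s, p)
                      = r_1 + sum_{i=1..d} (r_{i+1} - r_i) / (1 + e^{-s_i (x - p_i)}),

with degree `d` (the number of rate transition points), block rates `r >= 0`
(log scale), slope scalars `s >= 0` and increasing transition points
`p in [0, b_p]`.  Away from sharp transitions `Psi` sits at the enclosing
block's rate, and the slope at `p_i` is approximately `(r_{i+1} - r_i) s_i / 4`;
both facts are enforced as tests.

Counts are gamma-convolved Poisson (negative binomial):
`y ~ Pois(Lambda)`, `Lambda ~ Gamma(mean lambda, var zeta * lambda^2)`, so that
`Var(y) = lambda + zeta * lambda^2` and `zeta = 0` is exactly Poisson.  The
dispersion factor is estimated per (gene, cell type) by the moment identity
`zeta = var(y)/mean(y)^2 - 1/mean(y)`, floored at zero, from the observed
(real-level, non-empty) grid rows.  This pooled estimate deliberately absorbs
spatial signal into `zeta`; it is crude but conservative, and the package
treats it as a fixed plug-in rather than a parameter of the fit.

### Fixed effects, time series, random effects

Binary factors enter through a full factorial of interaction products
`w_j(xi)`, with the empty product as the baseline; each spatial parameter of
each block is a design-weighted sum `z_qi = sum_j w_j(xi) beta_qij`.  Rate
effects are natural-log fold changes of `lambda + 1` (divide by `log_e 2` for
the conventional log2 scale); point and slope effects are additive.  An
ordered time series is coded as cumulative binary indicators (a sample at
`T_m` activates all indicators up to `m`); time indicators interact pairwise
with each non-time factor but never with each other.

A single random-effect factor (replicate, animal, run) warps the spatial
parameters after the fixed-effect sum.  The warp
`omega(z, rho, b)` moves `z` smoothly toward `b` for `rho > 0` and toward 0
for `rho < 0`, stays inside `[0, b]`, and reduces to linear scaling
(`z (1 + rho^2)` or `z e^{-rho^2}`) as `b -> inf`, which is the form used for
rates and slopes; transition points warp against `b_p`.  Random effects are
shared across cell types and estimated relative to a synthesized pseudo
reference level ("none"): for every design cell, the pseudo count is
`round(e^m - 1)` with `m` the mean of `log_e(y+1)` across the real levels.

### Degenerate inputs and numerical choices

* Values produced by unconstrained effect sums are floored at `1e-8` (rates,
  slopes) or clipped to `[0, b_p]` (points) before warping; warped transition
  triples (point, slope, rise) are re-sorted if an extreme excursion breaks
  monotonicity.  The reordering makes the objective piecewise smooth; the
  optimizer restarts with fresh curvature memory when a line search stalls at
  such a kink.
* `Psi` is capped at 45 with a smooth quadratic penalty beyond the cap so the
  likelihood and its gradient stay finite while the optimizer explores.
* `lambda = 0` rows use the point-mass limit; `y > 0` at `lambda = 0` maps to
  a large finite negative log likelihood (-1e30) to keep line searches alive.
* Empty grid rows (no contributing cells) carry no likelihood weight but
  still receive predictions.

## Fitting

1. **Degree estimation.**  Counts are aggregated over interaction and real
   random levels into a per-bin profile.  Every interior split is scored by
   the two-segment minus one-segment profile-Poisson log likelihood ratio.  A
   split is flagged when it is a local maximum of the LR curve within a
   `min_gap` window and its dispersion-scaled statistic `2 LR / phi` exceeds
   a Bonferroni-corrected chi-square(1) quantile at level `10^-outlier_k`
   (`phi` is the Pearson dispersion of the one-segment fit, floored at 1).
   Flagged splits are accepted greedily in decreasing LR order subject to
   `min_gap` separation and a degree cap.  Defaults:
   `min_gap = max(3, n_bins/20)`, `outlier_k = 3`, `max_degree = 8`.  The
   dispersion scaling keeps the detector calibrated on over-dispersed
   profiles; a plain robust-outlier rule on the LR scan is miscalibrated in
   both directions because the scan is a smooth, strongly autocorrelated
   curve rather than noise with spikes.
2. **Initialization.**  Baseline rates start at segment means of
   `log_e(y+1)` over reference-level rows; points at the detected splits;
   slopes at `s_init = 5` (visible but not razor-sharp).  Treatment effects
   start at zero.  Random effects cannot start at zero — the warp depends on
   `rho` only through `rho^2`, so `rho = 0` is a stationary point of the
   likelihood for every random effect — so rate random effects are seeded by
   inverting the infinite-bound warp on each level's mean log-linked count
   deviation, and slope/point random effects start at 0.01 when the gene has
   transitions.
3. **Optimization.**  Each gene is optimized independently (the likelihood
   factorizes over genes) by L-BFGS-B on unconstrained internal coordinates:
   log-transformed baseline rates and slopes, scaled-logit transition points,
   raw treatment and random effects.  The gradient is analytic (validated
   against central differences in the test suite); a numeric fallback is one
   option away.  Defaults: gradient tolerance `1e-7`, relative function
   tolerance `2e-9`, 500 iterations.  A configurable Gaussian objective on
   `log_e(y+1)` is available behind `objective="gaussian-loglink"` but the
   count likelihood is the default and the recommended choice.

## Inference

Cells are resampled with replacement within (random level x interaction
combination) strata — stratification preserves the design — the grid is
rebuilt (including the pseudo level and per-resample empties), and the model
is refit warm-started from the full-data optimum with degrees and dispersion
held fixed, an iteration cap of 200, a single optimizer run (no kink
restarts) and a relaxed function tolerance of `1e-7` (percentile resolution
is limited by the number of resamples, not by optimizer precision).
Resamples are individually seeded from the master seed, so results are
identical for any worker count.

Per parameter: percentile 95% CIs over the converged resamples of its gene;
two-sided p-values for zero-centered parameters (fixed effects off the
baseline) by the smoothed sign-crossing formula
`p = 2 min(#{theta* <= 0} + 1, #{theta* >= 0} + 1) / (B + 1)`, capped at 1.
An exactly constant resample distribution — typically a clipped,
unidentifiable block effect frozen at its warm-start value, or a design so
degenerate that every resample reproduces the data — carries no
sign-crossing information and yields an undefined p-value, excluded from
adjustment and aggregation.  Multiplicity is handled by Holm
step-down (Bonferroni optional) over the family of all non-baseline fixed
effects in the model run; random effects get CIs but no p-values.
Significance tiers follow the ns / * / ** / *** convention at 0.05 / 0.01 /
0.001.

Metropolis–Hastings random-walk MCMC over the internal coordinates is
implemented but disabled by default: the exponential nonlinearities and
parameter boundaries make the likelihood landscape rocky, and the random
walk mostly performs poorly.  The proposal scale adapts toward 0.23
acceptance during burn-in.

## The attractor simulator

The benchmark needs data whose spatial structure, treatment effects and
replicate effects are known exactly and are generated *without* any WSP
machinery.  Starting from seed data (cells on a patch with over-dispersed
counts), one simulation:

1. shuffles all cell coordinates (erasing real structure),
2. picks spatially variable genes (each with probability 0.5, re-drawn until
   at least one) and pulls each SVG's transcript-bearing cells toward a
   uniform random attractor point: `coord <- attractor +
   (coord - attractor)(1 - delta u)`, `u ~ U(0,1)`, pull strength
   `delta ~ U(0.3, 0.9)` per gene (a clearly visible concentration without
   collapsing cells onto the attractor),
3. gives a random subset of the SVGs a treatment rate effect: multiplicative
   factor `1 +/- U(0.05, 0.5)` (at least 5% up or down),
4. per replicate (default 4, each observed in both conditions), applies a
   small affine coordinate perturbation (rotation <= 5 degrees, translation
   <= 2% of the patch, isotropic scale 1 +/- 2%) and a per-replicate rate
   scaling `e^eta`, `eta ~ N(0, 0.1)` — the true random effect — realized on
   integer counts by binomial thinning (decreases) or Poisson top-up
   (increases).

Pulls are applied to whole cells, gene by gene in panel order; a cell bearing
several SVGs ends up at its last pull, so co-bearing genes partially disturb
each other's concentration — a realistic nuisance that the tests account
for.  The synthetic seed generator replaces external seed files: 4000 cells
uniform on a 2x2 patch, four genes with per-cell mean counts (2, 10, 0.5, 3)
and dispersion factor 1 — spanning sparse to abundant markers with
MERFISH-like over-dispersion.  What the simulator does **not** emulate:
segmentation errors, cell types, spatially varying capture efficiency, and
gene–gene correlation beyond co-occurrence in cells; benchmark results say
nothing about robustness to those.

A radial coordinate transform (`x' = x cos(2 pi y / max y)`,
`y' = x sin(...)`) wraps the controlled axis onto the radial axis for tools
that model radial profiles; the radial distance of every transformed point
equals its original `x`, so the count distribution along the radius
reproduces the distribution along `x` exactly.  An optional compensation
step multiplies counts by radial distance and renormalizes (largest-remainder
rounding, totals preserved) to offset area dilution in 2-D density views.

## The benchmark

Each simulation is fit on the controlled axis binned into 50 equal-width
bins (condition as the single fixed factor, replicates as random levels),
with bootstrap inference.  The adapter caps the model degree at 2: a single
attractor produces at most a rise and a fall along a 1-D projection, and
higher degrees only chase binning noise with weakly identified extra
blocks.  Because the simulator applies one space-constant
rate effect while the model estimates one per block, per-gene aggregates are
used: the estimate is the mean of the block rate effects, and the gene-level
p-value is the mean of the raw block p-values divided by the number of
blocks, then Holm-adjusted across the simulation's genes — the same
per-gene-adjusted basis on which differential-expression and SVG comparators
report.  Decisions at `alpha = 0.05` are scored by the four-way FP/TN/TP/FN
rule; FPR = FP/(FP+TN), FDR = FP/(FP+TP), power = TP/(TP+FN), with empty
denominators reported as missing rather than zero.  Effect-recovery quality
is summarized by pooled Pearson correlations between estimated and true
fixed (per gene) and random (per gene and replicate) log-rate effects.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run the full pipeline at sizes a
single core handles comfortably: simulations of 4 genes x 4000 cells x 8
observations, 50 bins, 25+ simulations with 200 bootstrap resamples each;
calibration checks use a 1-gene, 15-bin toy with 100–500 resamples.  These
are the package's reference conditions for its own regression checks; the
machinery itself has no hard-coded scale.

## Known limitations

* One spatial dimension, one random-effect factor, binary fixed factors
  (plus ordered time series) only.
* The `rho^2` warp parameterization makes the likelihood non-identifiable in
  the sign of `rho` near zero and stationary at exactly zero; estimation
  relies on the data-driven initialization described above, and slope/point
  random effects with negligible signal stay near their small seed values.
* Greedy change-point acceptance can over-segment strong smooth gradients;
  blocks narrower than the data can support produce weakly identified block
  effects (their bootstrap distributions flag this by degenerating, which
  the p-value guard converts to non-significance).
* The moment dispersion estimate absorbs real spatial variation, which
  lowers power on strongly structured genes (a conservative failure mode).
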