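# Methods

## The design space

A 3-2-1 mediation design places the independent variable X at level 3
(clusters, e.g. organizations), the mediator M at level 2 (e.g. providers)
and the outcome Y at level 1 (e.g. patients).  A design is specified by

| input | meaning | default grid values |
|---|---|---|
| a3 | standardized between-level path X→M | 0.14, 0.39, 0.59 |
| b3 | standardized between-level path M→Y | 0.14, 0.39, 0.59 |
| c3p | standardized direct effect X→Y | 0.14, 0.39 |
| b2 | standardized within-level path M→Y | 0.39 (fixed) |
| icc_m3 | share of M variance at level 3 | 0.05, 0.10, 0.20 |
| icc_y2 / icc_y3 | share of Y variance at level 2 / 3 | 0.05, 0.10, 0.20 |
| n3 × n2 × n1 | clusters × units × observations | {10,20,40,60} × {5,10,20} × {3,6,12} |

Fully crossed this yields 17,496 designs.  b2 is modeled as a degenerate
one-value grid axis so it can be swept if desired.  n3 must be even so the
two arms are exactly balanced; odd n3 is rejected rather than silently
imbalanced.

## Generating model and standardization

All variables are Gaussian; total variances of M and Y are normalized to 1
so the ICC inputs are absolute variance shares.  X is coded −1/+1 with exact
half/half allocation (var(X) = 1).  The level-3 paths are standardized
*between level*: they act on the level-3 latent components scaled to unit
variance.  This is the multilevel-SEM convention, and it is the only one of
the candidate conventions under which every cell of the default grid maps to
a non-negative variance decomposition (with total-variance standardization,
a3 = 0.59 would demand more explained level-3 variance than icc_m3 = 0.2
provides).  The mapping is

    a_raw        = a3 √icc_m3            var_mB_resid = icc_m3 (1 − a3²)
    var_mW       = 1 − icc_m3
    b3_raw       = b3 √(icc_y3/icc_m3)   c_raw        = c3p √icc_y3
    var_yB_resid = icc_y3 (1 − R²_B),    R²_B = b3² + c3p² + 2 a3 b3 c3p
    b2_raw       = b2 √(icc_y2/(1 − icc_m3))
    var_y2_resid = icc_y2 (1 − b2²)      var_y1       = 1 − icc_y2 − icc_y3

Grand means are fixed at 0 (location does not affect power); intercepts are
still estimated.  The inverse mapping reproduces the standardized inputs to
1e-12 (property-tested), and the implied totals are exactly 1.

## Simulation

`generate` draws full datasets in a fixed order (cluster M effects, unit M
deviations, cluster Y residuals, unit Y residuals, observation residuals) so
a seed pins the dataset byte-for-byte.  Every estimator in the package
depends on the data only through per-cluster sufficient statistics (cluster
means of M and Y, within-cluster cross-products of M and unit-mean Y, and
the level-1 sum of squares), so the power engine samples these directly:
unit means of Y absorb a Normal(0, var_y1/n1) term and the level-1 SS is
drawn as var_y1·χ²(n2(n1−1)) per cluster.  This collapse is exact by
sufficiency — a paired test confirms the two paths agree in distribution and
in estimated power — and reduces the cost of the full default sweep
(17,496 × 500 ≈ 8.7M replications) to roughly four minutes on one CPU.

What the generator does *not* emulate: non-Gaussian or skewed outcomes,
unbalanced cluster sizes, missing data, covariates, and measurement models
for M or Y.  Passing tests therefore speak to power under the idealized
balanced Gaussian design, the standard setting for analytic power work, not
to robustness under real-data departures from it.

## Manifest estimation (MVM)

The X→M path comes from the 2-level random-intercept model
M = γ0 + a·X + u + r.  The Y model uses the mediator *centered within
context with means reintroduced*: Y on the observed cluster mean of M (level
3), the within-cluster deviation (level 2), and X, with random intercepts at
all three levels.

For balanced data with level-appropriate predictors the Gaussian likelihood
factorizes over three orthogonal strata — within-unit contrasts,
between-unit-within-cluster contrasts, cluster means — with eigen-variances
λ1 = σ1², λ2 = σ1² + n1σ2², λ3 = σ1² + n1σ2² + n1n2σ3².  ML is then exact
and closed form: stratum-wise OLS for the fixed effects and SS/df for the
λ's, followed by a weighted isotonic (pool-adjacent-violators) projection
onto λ1 ≤ λ2 ≤ λ3, which is ML on the boundary when a variance component
would go negative (the event is flagged, not fatal).  No iteration, no
convergence failures except genuine rank deficiency (e.g. the cluster means
of M collinear with X), which marks the replication non-converged.  The
closed form was verified against an independent iterative mixed-model fit:
point estimates agree to 1e-7 and the closed form attains a log-likelihood
at least as high.

Standard errors: the default is a cluster-level sandwich (each cluster
contributes one independent score; for this balanced design the sandwich
reduces to the HC0 estimator of the corresponding cluster-level regression),
the analogue of maximum likelihood with robust standard errors.  Model-based
inverse-information SEs are available via `se_method="ml"`.  Calibration
checks at 4,000 replications show both track the true Monte Carlo sampling
SD of the estimates (model-based within ~3%, HC0 ~9% low at 40 clusters).

Because the observed cluster mean of M carries within-cluster sampling error
(variance var_mW/n2), the manifest between slope is attenuated toward the
within slope,

    plim b̂3 = (b3_raw·τ + b2_raw·var_mW/n2) / (τ + var_mW/n2),  τ = var_mB_resid,

and the displaced effect surfaces in the direct path,
plim ĉ = c_raw + (b3_raw − b2_raw)·a_raw·(var_mW/n2)/(τ + var_mW/n2).  Both
limits are exported and simulation-verified.

## Latent estimation (MSEM-style)

The latent level-3 covariance of (X, M_B, Y_B) is estimated by unbiased
moments on balanced data: level-2 components from within-cluster deviations
(with the level-1 contribution var_y1/n1 removed from the Y variance via the
level-1 mean square), and latent level-3 (co)variances as between-cluster-
mean (co)variances minus (level-2 component)/n2; covariances with X need no
correction.  Paths are partial regression coefficients solved from these
matrices, so b̂3 is consistent for the unattenuated b3_raw.  A fit is
non-converged when the latent M_B variance estimate is ≤ 0 or the latent
predictor covariance is singular — the moment analogue of the convergence
failures full-ML multilevel SEM exhibits in small samples.

Standard errors come from a nonparametric cluster bootstrap (clusters
resampled with replacement, stratified by arm, default 200 draws, seeded
from the replication substream).  The latent slope is a ratio whose
denominator can approach zero in a resample, so the bootstrap distribution
is heavy-tailed and its raw standard deviation is dominated by a handful of
degenerate draws; the SE is therefore the normal-consistent interquartile
scale IQR/1.349 of the bootstrap distribution.  This choice keeps the MSEM
test usable across the grid while preserving the qualitative ordering the
design comparison is about: the latent estimator trades its unbiasedness for
larger SEs and lower power than the manifest estimator.  It remains a
method-of-moments + bootstrap stand-in for full-information ML multilevel
SEM, and its power is expected to sit below what a full-ML implementation
would report.

## Inference

The Sobel first-order delta test: se(âb̂) = √(â²se_b² + b̂²se_a²),
z referred to the standard normal (1.959964 / 1.644854 at α = 0.05; no df
correction).  One-sided decisions reuse the stored two-sided z — reject iff
direction·z ≥ z₁₋α — so no refitting is needed.  A z exactly at a critical
value counts as a rejection (deterministic tie-break).  The hypothesized
direction defaults to +1, the sign of every non-null indirect effect in the
default grid.  Under a true null the test is conservative (empirical type-I
error ≈ 0.004 at α = 0.05 with 20 clusters), as expected for the delta
method applied to a product of coefficients.

## Power engine

Power for a design = rejections / completed replications (non-converged
replications are excluded from the denominator and reported, so the
out-of-requested reading can also be formed).  Defaults: 500 replications,
α = 0.05, adequacy threshold 0.8 — all parameters.  The binomial Monte Carlo
SE √(p(1−p)/reps) is attached to every estimate (±0.018 near p = 0.8 at 500
reps), so near-threshold classifications flip across seeds; grid-level
"adequate" counts inherit a seed-to-seed spread on the order of ±12 designs.

Randomness is organized as counter-based `SeedSequence` streams keyed by
(run seed, design key, stream, counter), where the design key is a stable
hash of the design's canonical JSON.  Replications are simulated in chunks
whose size depends only on the design dimensions, so any execution order or
worker count reproduces the same numbers; a grid sweep can be checkpointed
to CSV and resumed bit-identically.  Within-design replication batches share
a stream; isolating a single replication means regenerating its chunk.

Summaries mirror the two standard reporting layouts: a census of adequately
powered designs by each design characteristic and by total sample size, and
a minimum-sample-size table that picks, per design cell, the lexicographically
smallest adequate allocation — smallest n3 first, then n2, then n1 — because
clusters are the costly unit to recruit.  Cells are keyed by
(icc_m3, icc_y3, a3, b3, c3p) by default; fields outside the key (icc_y2)
are marginalized, i.e. a sample-size combination qualifies if any of its
designs in the cell is adequate.

## Known limitations

* The MSEM-style estimator substitutes moments + bootstrap for full-ML
  multilevel SEM; its absolute power is lower than a full-ML implementation
  would give, so MSEM-based counts are indicative, not calibrated.
* Manifest-model power here runs a few percentage points below figures
  produced by some other software near the adequacy threshold; our SEs are
  calibrated against the true sampling variability (see the MVM section), so
  threshold-sensitive counts (e.g. "designs with power ≥ 0.8") should be
  read with the Monte Carlo and estimator caveats above.
* Only balanced designs with continuous Gaussian M and Y, two-arm
  cluster-level X, and no covariates are in scope; 3-3-1/3-1-1 layouts,
  random slopes, moderated mediation and resampling-based mediation tests
  are not implemented.
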