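# Methods

This note documents the statistical procedures the package implements, the
defaults it ships with and why, what the synthetic generator does and does not
emulate, and the numerical conventions a user should know before trusting an
edge case.

## Census structure and block aggregation

The unit of analysis is a 1 km × 1 km block holding up to nine 333 m
sub-blocks, observed in two census years on both sides of a reserve boundary.
All distances are in kilometres and signed — negative inside the reserve,
positive on pastoral land — so one axis carries the whole human-use gradient;
coordinates are planar metres.  Blocks with `Q < 9` censused sub-blocks (grid
edges, inaccessible terrain) would bias plain sums low, so species totals are
expected-value corrected by `9/Q`.  These totals are kept as reals: they are
integers exactly when `Q = 9`, and the diversity estimators round half-up
only where integer frequencies are required (the jackknife), while Hill
numbers use the unrounded proportions.  Covariate means use the non-missing
sub-blocks; presence flags (fire scars, sheep/goats, cattle, carnivores,
vehicles, litter) OR to the block.

## Kriging imputation

Vegetation attributes are observed on a planned subset of sub-blocks (grass
attributes in sub-blocks 1, 4, 7; shrub and tree attributes in the central
sub-block 5).  Each variable is imputed independently by ordinary kriging:

* empirical semivariogram `γ(h) = ½·mean[(z_i − z_j)²]` in 12 lag bins up to
  half the maximum pair distance (bins without pairs are dropped);
* weighted least-squares fit (weights = pair counts) of spherical,
  exponential and gaussian models with practical-range parameterization; the
  family with the smallest weighted residual wins; non-convergence falls back
  to a pure-nugget model with a log warning;
* per-target ordinary-kriging solve over the ≤ 64 nearest observations
  within twice the fitted range; duplicated coordinates are averaged before
  the solve.  Weights sum to one by construction and prediction at an
  observed location with zero nugget reproduces the observation exactly.

Variogram estimation subsamples at most 2,000 observed points (the full
pair set is quadratic); bounded covariates (percent cover, color scores) are
clamped to their ranges after prediction because the kriging predictor is
unconstrained.  Observed values are never overwritten, and a provenance
column (`observed | imputed`) records what was filled.

## Diversity estimation

Hill numbers `^qD = (Σ p^q)^(1/(1−q))` are reported at orders 0, 1
(exp-Shannon, the continuous limit), 2 (inverse Simpson), 10 (evenness-heavy)
and ∞ (reciprocal Berger–Parker; undefined when several species tie for top
abundance, following the tie rule of the field protocol this mirrors).

Imperfect detection biases richness low.  The bias adjustment has two parts:

1. **Unseen-species count** from the Burnham–Overton generalized jackknife.
   The order-k estimator is `Σ_j c_j T_j`, where `T_j` is the expected
   richness after removing j individuals and the `c_j` cancel bias terms
   `1/(n−j)^r`, r = 1..k; the package solves this small system in exact
   rational arithmetic (orders up to 5).  The order is chosen sequentially:
   order 0 iff there are no singletons; otherwise start at order 1 and raise
   the order while the increment to the next order is significantly positive
   (normal test at α = 0.05 with the Burnham–Overton variance), stopping on a
   degenerate zero-variance increment.  No interpolation between orders is
   applied; the chosen integer order is reported alongside the estimate,
   which is floored at the observed richness.
2. **Unseen probability mass** from the Chao-modified Turing coverage
   `C = 1 − (f₁/n)·((n−1)f₁/((n−1)f₁ + 2f₂))`.  Observed proportions are
   scaled by `C` and the deficit `1 − C` is spread uniformly over the
   jackknife's unseen species (a possibly fractional effective number,
   treated as a uniform measure).  All orders, including ∞, are evaluated on
   this one adjusted measure, which keeps the profile nonincreasing in `q`
   by the power-mean inequality.  With no singletons the coverage is 1 and
   every order reduces to the raw Hill number.  The coverage is floored at
   0.5: communities made entirely of singletons give a degenerate Turing
   estimate, and an adjustment claiming more unseen than seen mass is not
   defensible from one census.

Diversity is computed over the wild species pool only; livestock enter the
models as covariates.  Unit weights (kg per individual) ship as a
configurable species-attribute table following the standard savanna-ungulate
literature values; wildebeest and zebra carry the migratory flag by default.

## Response families

Three families cover the response types, each parameter with its own link:

* **NB** (raw richness): mean–dispersion parameterization,
  `Var = μ + σμ²`, log links.  As σ → 0 the pmf approaches Poisson(μ).
* **Zero-truncated NB** (bias-adjusted richness, which has no zeros):
  `log f(y) = log NB(y) − log(1 − NB(0))`, support y ≥ 1.
* **Zero-adjusted gamma** (biomass and diversity orders): point mass ν at
  zero (logit link), gamma with mean μ and coefficient of variation σ on the
  positive part (log links).  Diversity orders 1/2/10 are bounded below by 1
  and contain exact ones, so they are fitted with `shift = 1`: one is
  subtracted before fitting (the ones land in the zero part) and added back
  to predictions; biomass uses shift 0.  The predicted mean is
  `(1 − ν)·μ + shift`.

All gradients of the log-likelihood with respect to the linked predictors are
analytic (digamma terms included) and are verified against central finite
differences at 1e−6; normalization is verified by summation/quadrature at
1e−8 or better.  A Gaussian location–scale family is included as a
transparent reference for algorithmic tests (its boosting limit is ordinary
least squares).

## Boosting

Non-cyclical component-wise functional gradient boosting: per iteration, the
score vector of every distribution parameter is computed at the current fit;
every candidate base learner is fitted to its parameter's score by penalized
least squares; within each parameter the learner with the best gradient fit
is the candidate, and across parameters the candidate whose step-damped
update most reduces the empirical negative log-likelihood is the one applied.
Ties break to the lowest learner index.  If no candidate lowers the risk the
algorithm stops and flags the model, which makes the training-risk path
nonincreasing by construction (asserted in tests).

Defaults, exposed in the API/config:

* P-splines: cubic B-spline basis on 20 equally spaced interior knots,
  second-order difference penalty, penalty weight solved so the effective
  degrees of freedom (trace of the learner hat matrix) equal 4.  Metric
  predictors get one P-spline learner per grouping cell; binary predictors a
  linear learner (intercept + standardized slope, unpenalized, df 2);
  predictors constant within a cell are dropped with a warning.
* Step length 0.1 — the conventional shrinkage in component-wise boosting.
* Offsets: unconditional maximum-likelihood estimates per distribution
  parameter on the link scale.
* The scale parameter σ is a nuisance: it receives an intercept learner only
  unless `model_sigma_covariates` is set; covariate learners attach to μ and
  (for the zero-adjusted gamma) ν.
* Variable coefficients ("fit predictors separately by land use and census
  year") are separate base learners per cell rather than interaction bases,
  so each cell accumulates its own coefficients and selection frequencies.
* Early stopping: 25 (default; fewer where configured) random 80/20
  subsamples stratified by the grouping cells, out-of-sample mean NLL per
  iteration, `mstop` = argmin of the column means.  Subsampling was chosen
  over k-fold because it is the scheme the stability-selection stage uses
  anyway; the resample count, fraction and scheme are configurable.

## Stability selection

Complementary-pairs subsampling: B/2 random half/half splits (B = 50 halves
by default), each half boosted until `q_sel = 6` distinct covariate learners
have been selected (intercept learners do not count; runs that never reach
the budget within the iteration cap are flagged and removed from the
denominator).  A candidate is one (parameter, learner) pair; a predictor is
*stable* when its selection frequency reaches π = 0.7 — a closed threshold,
0.69 is out — on the location (μ) or zero-part (ν) parameter.  Scale-(σ-)
frequencies are reported but never confer stability.  The per-family
expected false-positive bound `PFER ≤ q²/((2π−1)p)` is reported with every
result and verified empirically on all-noise designs in the test suite.

## Gradient prediction

Curves are predicted on a 0.5-km distance grid spanning the observed range
(finer steps add nothing below the 1-km block size).  Metric covariates are
held at their medians (robust to the skewed distributions of distances and
rainfall), categorical/presence covariates at zero, and the census-year cell
is set explicitly.  Predictions outside the observed distance range are
refused unless explicitly allowed, because P-spline fits carry no information
beyond the data (the basis is clamped at the training range).  Peak = argmax
with flat maxima resolved to the smallest distance, for determinism.
Drought-vs-normal comparisons report the per-distance percent change
`100·(A−B)/B`, masked where the reference is zero.

## The synthetic generator

`simulate_landscape` emulates the data-generating structure the analysis
assumes, with defaults that define the package's study conditions:

* 30 × 30 blocks (9 sub-blocks each), boundary at column 15, so signed
  distances span −14.5 … +14.5 km at block centres;
* a 19-species pool with geometric rank abundance (shape 0.4), the two top
  ranks being the migratory wildebeest and zebra — the two of them carry
  ~64 % of individuals;
* per-species block intensity = pool abundance × a Gaussian *biomass kernel*
  in signed distance (default peak −15 km, width 12 km) × the *year
  multiplier* (0.5 in the drought year) × lognormal block heterogeneity
  (sd 0.5 on the log scale);
* occupancy: migratory species follow the biomass kernel
  (`0.25 + 0.75·g_bio`), resident species have rank-decaying floors lifted
  toward 1 by a Gaussian *diversity kernel* (default peak +5 km, width 6 km),
  damped by √(year multiplier) in the drought year.  Expected block richness
  is therefore an almost exact Gaussian bump at the configured peak (the
  migratory term adds a ≈0.2 km pull toward the reserve);
* counts: present species draw zero-truncated Poisson totals around their
  intensity, placed multinomially over the sub-blocks that are not
  *structurally empty*.  The structural-empty probability per sub-block is
  calibrated by bisection against the exact expected zero fraction so the
  realized share of empty sub-blocks hits the per-year targets (73 %
  drought, 63 % normal, the regime such censuses show).  Because placement
  only moves animals between sub-blocks, block totals are independent of the
  calibration and the drought multiplier reappears as a ~50 % biomass
  decline.  An unreachable target (below the floor implied by the count
  intensities) raises a calibration error;
* covariates: nine vegetation fields (Gaussian random fields with 5–8 km
  correlation ranges, drought shifts for grass attributes, planned
  missingness per the plot design), elevation/slope, distances to water,
  occupied/abandoned bomas (pastoral-side point processes) and
  infrastructure, three rainfall components per year, and six presence flags
  with land-use-dependent rates (livestock penetrating ~7 km into the
  reserve) — about 26 block-level predictors;
* incomplete blocks: 18 % (drought) / 29 % (normal) of blocks lose 1–3
  random sub-blocks, exercising the 9/Q correction.

`write_truth` emits the latent per-(block, year) quantities — expected
richness Σπ, expected counts and biomass at unit heterogeneity, total
intensity, the configured peaks — for parameter-recovery tests.

**What the generator does not emulate**, hence what passing tests do not
show about field data: counts are independent across species and sub-blocks
given the block intensity (no herding/clustered placement, which would
inflate overdispersion beyond the lognormal block effect); detection is
implicit in the occupancy/zero calibration rather than covariate-dependent
(no vegetation-driven visibility bias); migratory block-level biomass zeros
come out near 25–30 %, lower than the 52–62 % such systems can show, because
the migratory occupancy floor is 0.25; biomass is dominated by the top ~10
of 19 species (heavy rare browsers carry extra mass) rather than ~7; and
block-level zero fractions are an emergent property, not a calibrated one —
only the sub-block 73 %/63 % targets are controlled.  Rainfall fields are
smooth synthetic surfaces, not extracted raster data, and no shapefile
geometry exists: boundary distances are emitted directly.

## Problem sizes and numerical conventions

The shipped verification runs use sizes chosen to exercise every code path
at desk scale: identity checks on 1,000 random abundance vectors, jackknife
agreement on 200 vectors, ML recovery at n = 10,000 per family, the
PFER null check on 50 replicate 400 × 20 designs, and the end-to-end
recovery study on twenty 30 × 30 landscapes with fixed mstop = 300 (the CV
stage is exercised separately and once in the acceptance script; a fixed
budget keeps the 20-seed study's selection pressure identical across seeds).
Link-scale predictors are clamped at ±30 before inverse links; penalized
least-squares solvers add a 1e−9-scale ridge for rank safety; kriging
systems fall back to the pseudoinverse on singularity; the zero-truncated NB
renormalization uses `log1p(−P₀)`; and every stochastic routine takes an
explicit seed, with the pipeline deriving per-stage seeds from one global
seed so stages can be rerun in isolation.

## Known limitations

Bias-adjusted Hill numbers at interior orders rest on the uniform-unseen
assumption above — a convention, not an estimate of how unseen mass is
distributed.  The jackknife order selection is the classical sequential
procedure and inherits its known variance underestimation at small n.
Stability selection's PFER bound assumes exchangeable noise predictors;
with strongly correlated covariates it is conservative for some predictors
and not for groups.  Kriging is per-variable ordinary kriging: no trend
surfaces, no anisotropy, no co-kriging of related vegetation attributes.
The boosting implementation supports linear and P-spline learners only — no
trees, no spatial or random-effect learners — and model comparison across
families is by design out of scope (family choice follows the response type).
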