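# Methods

## Model family

All six models share a Gaussian observation model with identity link,

    y_it ~ Normal(eta_it, sigma^2),
    eta_it = beta_0 + sum_m beta_m x_mit + sum_l f_l,

over counties *i* and census years *t* (default censuses 1997, 2002,
2007, 2012).  The response is relative insecticide use in [0, 1]; no link
transformation or clipping is applied, matching the Gaussian-likelihood
convention of this literature.  The fixed covariates, with the unit
conventions chosen so published per-unit slopes apply directly:

| covariate | meaning | units |
|---|---|---|
| `x_corn` | share of harvested cropland in corn grain/silage | proportion |
| `x_cov`  | share in cotton, orchards, vegetables | proportion |
| `x_sw`   | share in soybean and wheat | proportion |
| `x_income` | net farm income per harvested hectare | thousand USD/ha |
| `x_size` | harvested cropland per operator | km^2 (= 100 ha) |
| `x_gdd`  | annual growing degree days | thousands of degree-days |
| `x_crop` | proportion of county land in harvested cropland | proportion |

Year enters as a centered continuous covariate in calendar-year units
(1997 -> -7.5, ..., 2012 -> +7.5), so its slope is a per-year trend.

Random-effect blocks: exchangeable county and year intercepts, and
separable space-time ("CAR x AR1") blocks whose precision is the
Kronecker product of a stationary unit-marginal-variance AR1 precision
over years and the intrinsic CAR (Besag) structure matrix `D - W` of the
county adjacency graph, scaled by a block precision tau.  The ICAR
structure is left unscaled (no generalized-variance rescaling), matching
the default behaviour of the software era this design reproduces.  The
improper directions (one per connected component per year) are removed by
sum-to-zero constraints over counties within each year and component.
Isolated counties form their own components; their variation is carried
by the exchangeable county intercept.

Priors: Normal(0, precision 0) on the intercept, Normal(0, precision
0.001) on all other fixed effects, Gamma(1, 0.00005) on every precision
(equivalently Log-Gamma on the log precision), and Normal(0, precision
0.15) on the transformed AR1 coefficient `theta = log((1 + rho) / (1 -
rho))`.  The rho prior is stated in the source material only as
"Normal(0, 0.15)"; placing it on the log-odds transform is the standard
internal convention of the reference software and is adopted here.

## Inference

A blocked Gibbs sampler alternates:

1. **Joint Gaussian draw** of `(beta, all latent blocks)` from the full
   conditional `N(Q^-1 b, Q^-1)` with `Q = Z'Z / sigma^2 + P(hyper)`.
   `Q` is assembled as a weighted sum of pre-aligned sparse components
   (so only coefficient vectors change per sweep) and factorized either
   by dense Cholesky (joint dimension <= 250) or by SuperLU in symmetric
   mode without pivoting, which yields an exact L L' factorization for
   SPD matrices.  A draw uses the identity `Q^-1 (P' L z) ~ N(0, Q^-1)`,
   so sampling costs one factorization plus solves.  Sum-to-zero
   constraints are imposed exactly by conditioning-by-kriging
   (`x - Q^-1 C' (C Q^-1 C')^-1 C x`).
2. **Conjugate Gamma draws** of the error precision and each block
   precision; space-time blocks use the rank `T (n_counties -
   n_components)` of their improper prior in the shape update.
3. **Random-walk Metropolis** on each transformed AR1 coefficient, using
   the closed-form determinant `|Q_AR1(rho)| = (1 - rho^2)^-(T-1)` and
   precomputed quadratic forms so proposals cost O(1).  Proposal scales
   adapt toward 0.44 acceptance during burn-in only, preserving the
   chain's invariant distribution afterwards.

Degenerate directions: the flat intercept prior is exactly confounded
with the constant mode of an improper space-time block, so the
unconstrained `Q` is singular.  A diagonal jitter of 1e-8 times the
largest diagonal entry is added to space-time blocks before
factorization; the constraint correction then conditions those modes
away, leaving an O(1e-8) relative perturbation of the sampled law.  The
factorization raises a clear error if the precision is not SPD after
this.

Defaults: 10,000 iterations, 2,000 burn-in, thinning 5, all configurable;
chains are bit-reproducible given the seed (PCG64).  Experiments in the
test suite and acceptance script use shorter chains (600-1,500
iterations) on 8x8 to 10x10 lattices so the full suite runs on one CPU in
minutes; those sizes are stated with each experiment.

## Model comparison and diagnostics

* **DIC**: `deviance(theta) = -2 log N(y; mu, sigma^2)`; `pD = mean
  deviance - deviance at the posterior means of mu and sigma^2`; `DIC =
  mean deviance + pD`.  `pD` can be negative in pathological fits and is
  reported as computed.  Delta-DIC subtracts the minimum across models.
* **PIT**: two variants are computed.  `compute_pit` is the
  posterior-predictive transform `E_draws[Phi((y_i - mu_i)/sigma)]`.
  For calibration checks this is misleading in the flexible models: a
  county-year latent field fits each observation closely (pD of order
  n/2), concentrating posterior-predictive PIT near 0.5 even when the
  model is true.  `FitResult.pit` therefore holds a leave-one-out PIT
  computed from the exact Gaussian cross-validation identity — given the
  hyperparameters, `p(y_i | y_-i)` is Gaussian with precision
  `d_i = 1/sigma^2 - Var(mu_i | y)/sigma^4` and standardized residual
  `a_i / sqrt(d_i)` with `a = (y - Z m)/sigma^2` — averaged over a
  subsample (default 20) of hyperparameter draws.  This matches the
  leave-one-out character of the diagnostic in the reference software
  and is uniform under the true model.  A plain importance-sampling LOO
  estimator was evaluated and rejected: with one latent effect per
  observation its weights are too heavy-tailed to be usable.
* **Residuals** are posterior-predictive means minus observations.
  Empirical variograms use Euclidean centroid distances, 15 equal-width
  bins to half the maximum pairwise distance (both configurable), one
  census year at a time.  Matern fits minimize a weighted least-squares
  objective (weights = pair counts / squared empirical semivariance)
  over nugget, partial sill and range, with smoothness selected from
  {0.5, 1.5, 2.5}; fits are deterministic (fixed multi-start grid).  An
  all-zero variogram short-circuits to a flagged nugget-only fit.

## Synthetic data

The generator emulates the structure of the national county panel on a
rook-adjacency grid with unit (1 km) centroid spacing, states as 5x5
blocks of counties.  Covariates are logistic or (log-)affine transforms
of smooth Gaussian fields: an ICAR draw (exact, via eigendecomposition of
`D - W` restricted to its positive subspace) plus iid jitter, shared
across years, plus a smaller independent smooth perturbation per year.
Locations and scales were chosen once to match the published descriptive
ranges (mean response ~0.25, mean cropland ~0.29, income ~0.61 thousand
USD/ha with occasional losses, farm size log-normal around ~1.2 km^2,
GDD ~0.5-6 thousand).  Crop shares are jointly rescaled where their sum
would exceed 0.95.  The response is drawn from the chosen generative
model (1, 4, 5 or 6) with fixed effects defaulting to the published
Model 6 posterior means, residual SD 0.054, AR1 coefficient 0.708, and
random-effect SDs 0.005 (county), 0.008 (year), 0.150 (space-time
scale).  Space-time fields are drawn exactly in the Kronecker eigenbasis
and satisfy the sum-to-zero constraints by construction.

Covariate censoring (masking with the `censor_prob` probability per
entry) emulates anonymity suppression in the source census; its default
is 0 — censoring is exercised explicitly where the imputation path is
under test, rather than folded into every experiment.

What the generator does not emulate: real county geography and irregular
adjacency degree distributions, survey sampling design, crop price
dynamics, covariate measurement error, and any dependence of censoring
on farm counts.  Passing recovery tests therefore demonstrates internal
consistency of the estimator under the assumed model on a regular
lattice, not robustness to the ways real census data violate it.

## Numerical and design choices

* Effect translations round half away from zero, matching how the
  published worked examples were rounded (e.g. 0.075 -> 0.08).
* Standardized coefficients multiply the posterior-mean slope by the
  covariate's standard deviation only (not additionally divided by the
  response SD); the published raw/standardized pairs are consistent with
  this convention, and a flag switches to the response-scaled variant.
* The 3% cropland filter defaults to the county level — a county whose
  mean cropland proportion across censuses is below 0.03 is dropped from
  all years — with a per-record mode available; the source material says
  counties were removed but not which years enter the rule.
* The minimum-cropland filter runs after imputation and before
  centering; this order is fixed and the pipeline helper enforces it.
* The quadrature oracle used in tests integrates the conditional
  Gaussian posterior over the error precision on a 3,000-point
  log-precision grid; it shares no code with the sampler.

## Known limitations

* Inference is MCMC; agreement with deterministic-approximation software
  is validated statistically against closed-form oracles, not to machine
  precision, and published DIC values from the full national panel are
  not reproducible from synthetic lattices.
* Gibbs mixing degrades for near-saturated designs (n close to the
  number of fixed effects); the test suite documents one such case
  needing a long thinned chain.
* On small lattices the cropland slope is spatially confounded with the
  CAR x AR1 intercept field, inflating its posterior spread; frequentist
  coverage of its credible intervals is slightly below nominal at small
  grid sizes.
* Variogram defaults (binning, maximum distance, smoothness candidates)
  are package choices, documented rather than inherited.
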