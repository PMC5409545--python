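# Methods

This note records the modelling assumptions, parameter choices and numerical
decisions behind `radonmap`, and what the synthetic validation does and does
not demonstrate about real data.

## The synthetic radon field

Indoor radon surveys are strongly right-skewed: most dwellings measure low,
a few measure extremely high. The generator models log-radon as a Gaussian
random field on a regular grid (1 km spacing by default), so concentrations
are lognormal. The calibration helper fixes the two free moments from the
survey summaries the workflow is built around: a geometric mean of
49 Bq/m³ sets the log-mean, and a target sample skewness of 7.84 sets the
total log-variance through the lognormal skewness identity
(w + 2)√(w − 1) = γ₁ with w = exp(σ²), giving σ² ≈ 1.175. No single
lognormal can simultaneously match that skewness and an arithmetic-to-
geometric-mean ratio of 62/49 (which implies σ² ≈ 0.47); the generator
prioritises the geometric mean and the skewness, accepting a larger implied
arithmetic mean. The total variance is split between a spatial variogram
sill and optional iid measurement noise; the sill splits again into a nugget
fraction (default 0.3) and a partial sill.

Defaults: spherical variogram, range 4 km on a 50 × 50 km default domain.
The short range relative to the domain mirrors a national survey, where the
exposure field decorrelates at scales far below the country extent; it also
keeps the realisation-to-realisation variability of the domain-wide
geometric mean small (each 50 × 50 realisation lands within roughly ±10% of
the 49 Bq/m³ target; the ensemble geometric mean over ten seeds is within
±1). Field simulation uses dense Cholesky factorisation of the covariance
C(h) = sill − γ(h) and is limited to 10,000 cells; larger grids are out of
scope for this desk-scale generator.

Survey sampling draws cells uniformly (with replacement by default, matching
a 5553-point survey on a 2500-cell grid), places each point uniformly within
its cell, and attaches the cell's field value plus optional log-scale
measurement noise. An optional clustering factor biases sampling towards a
few hubs; it is off by default because the original multi-survey sampling
design is not modelled.

## Regions, strata and counts

Regions are grown from random seed cells into a contiguous partition
(default 234 regions, matching the administrative geography the analysis
emulates); rook adjacency between regions sharing a cell edge defines the
CAR graph, which is connected by construction and verified. A deterministic
block mode exists for tests.

Stratified populations use a fixed age pyramid over seventeen 5-year bands
(0–4 … 80+) and an even sex split, with region totals lognormal around
172,857 (the observed regional mean, spread chosen to span the observed
range of roughly 10,000 to 1,000,000). Two built-in reference-rate tables
cover the outcome archetypes: a lung-cancer-like table rising steeply with
age and male-dominant, and an NHL-like table that is low and flat. Observed
counts are Poisson draws from the same log-linear BYM model the inference
stage fits — intercept, radon per 10 Bq/m³, optional covariate effects,
an ICAR draw u (sampled exactly on the sum-to-zero subspace via the
eigendecomposition of the graph Laplacian, scale σ_u) and iid v (scale σ_v)
— with the full ground truth stored alongside the data.

Deprivation enters as a standard-normal z-score and smoking as sex-specific
rates drawn uniformly over the observed regional ranges (male 31.9–62.4%,
female 0.4–12.5%). By default their true effects are zero, so crude and
adjusted fits should agree; both are exposed for confounded scenarios.

## Geostatistics

- Sample skewness is the adjusted Fisher–Pearson coefficient
  G1 = g1·√(n(n−1))/(n−2).
- The empirical semivariogram uses equal-width right-inclusive bins up to
  half the domain diagonal by default; empty bins are flagged, never
  interpolated; exactly coincident pairs accumulate into a separate
  zero-lag (nugget) estimate and never enter positive bins.
- Variogram fitting minimises Cressie-weighted least squares,
  Σ N_k (γ̂_k − γ_k)²/γ_k², with bounds c₀ ≥ 0, c ≥ 0, a > 0 and three
  starts; non-convergence raises an error carrying the best iterate.
- Ordinary kriging solves the standard (k+1) augmented system per target;
  exactly coincident data points are first averaged on the log scale (this
  matches the annual-average semantics of repeated measurements at one site
  and prevents singular systems). The search neighbourhood is the nearest
  16 points within 3× the variogram range; a cell with no neighbour in
  radius falls back to the global log-mean with σ² = sill and is flagged.
- The back-transform ẑ = exp(ŷ + σ²_OK/2 − μ_L) is the ordinary-kriging-
  consistent unbiased lognormal estimator; the Lagrange-multiplier term is
  what distinguishes it from the simple-kriging form. Leave-one-out on
  calibrated synthetic fields (500 points, five seeds) reproduces the mean
  concentration within 5%, while the naive exp(ŷ) underestimates by ~30% —
  the practical argument for lognormal kriging with this correction.
- Regional aggregation is the unweighted mean of cell estimates (cells are
  equal-area). Coordinates are planar projected km throughout.

## Standardization

Expected counts use indirect standardization. Reference rates default to
internal (pooled over all regions) rates, under which ΣO = ΣE exactly and
the E-weighted mean SIR is 1; external rate tables can be supplied. The
denominator is a single population snapshot, not accumulated person-years,
so SIRs are internally consistent ratios rather than absolute rates —
mirroring the registry convention of the workflow this package implements.
Sex-specific and age-restricted analyses (e.g. under-20) filter strata
before rates are derived, so strata are never mixed across sexes.

## The BYM model and sampler

The likelihood, priors and hyperpriors are given in the README. Design
choices:

- Convolution (u + v) rather than pure CAR: region-level extra-Poisson
  variation is ubiquitous in disease mapping, and the unstructured term is
  removable by configuration (`include_v=False`).
- Gamma(0.5, 0.0005) precision hyperpriors, the long-standing disease-
  mapping convention for weakly-informative precision priors, exposed in
  the model specification.
- Deprivation quintiles are assigned by rank (stable sort, ties broken by
  input order), giving group sizes that differ by at most one (47/47/47/47/46
  for 234 regions); quintile 1 is the reference and empty indicator columns
  are dropped with a warning.
- Sexes are fitted as separate models, not interacted.

The sampler is Metropolis-within-Gibbs with three non-obvious but
posterior-preserving accelerations:

1. **Internal centring.** Covariates are column-centred during sampling and
   the reported intercept shifted back. The raw intercept and the radon
   coefficient are nearly collinear (the radon column has a large mean), and
   random-walk updates on the raw parameterisation stall.
2. **Interchange moves.** After each coefficient update, a joint move
   (β_j, u) → (β_j + d, u − d·x_j^c) leaves the linear predictor — hence the
   likelihood — unchanged and is accepted on the ICAR-prior and coefficient-
   prior ratio alone; an analogous move trades β_j against v. These traverse
   the ridge created by spatially smooth covariates, which single-site
   updates cross extremely slowly.
3. **Scale-tracking proposals.** Proposal standard deviations for u and v
   are a tuned multiplier times the current conditional prior scale
   (1/√(deg_i·τ_u), 1/√τ_v), so step sizes follow the precisions as they
   evolve; multipliers adapt by Robbins–Monro towards 0.44 acceptance during
   burn-in only, preserving detailed balance afterwards.

u is recentred to sum to zero after every sweep with the shift absorbed into
the intercept (likelihood-invariant; the ICAR density depends only on
pairwise differences). Precisions are updated by their conjugate Gamma
conditionals. Chains start over-dispersed via chain-indexed offsets on the
intercept and coefficients. With these moves the reduced protocol
(5 chains × 4,000, burn-in 1,000, thin 5) reaches R̂ < 1.05 and effective
sample sizes above 1,000 for the radon coefficient on 200-region problems;
the 2-region intercept-only model matches its Gamma closed form within 2%.

Convergence is summarised by the Gelman–Rubin statistic in the form
R̂ = √(((n−1)/n·W + B/n)/W) with W the mean within-chain variance and
B = n·var(chain means), both with denominator n−1. Posterior summaries use
equal-tailed 2.5/97.5% quantiles with linear interpolation; RR quantiles are
the exponential of log-scale quantiles (monotone transform), the RR point
estimate is the posterior mean of exp(β).

## Parameter recovery and spatial confounding

The recovery experiment embeds a known relative risk (1.07 per 10 Bq/m³ by
default — the magnitude of the female-NHL scenario whose structure the
default conditions mirror) and refits it on 20 fresh synthetic maps of 200
regions. Conditions: NHL-like flat rates with paper-scale populations,
giving moderate expected counts (E_i ≈ 80); a 60 × 60 km domain, much larger
than the 4 km exposure correlation range; σ_u = 0.1, σ_v = 0.05; the true
regional radon means as the covariate, so the experiment isolates the
inference stage from interpolation error. Under these conditions the 95%
credible interval covers the truth in ≈ 90–95% of replicates and the median
log-RR bias is below 10⁻³.

The moderate-counts condition is not incidental. With very large expected
counts (E_i in the many hundreds) the Poisson likelihood becomes so sharp
that the dominant error source is *spatial confounding*: the smooth exposure
surface and the ICAR field live on the same geometry, chance alignment
between a realised u and the radon pattern shifts the identifiable
coefficient, and the model — which explains realised residual structure
through û — reports intervals narrower than the frequentist spread of the
estimator. The effect is a property of the design, not of the sampler: a
plain Poisson GLM shows the same attenuation outliers. At moderate E_i the
likelihood width dominates the confounding term and interval calibration is
restored. Users fitting sharp-likelihood problems with smooth covariates
should expect credible intervals for ecological exposure effects to be
optimistic; this is a known limitation of CAR-adjusted ecological
regression, not something post-hoc widening can fix honestly.

## What the synthetic validation does not show

The generator matches the marginal skewness, the spatial-correlation
structure, the regional population scale and the count-generating model of
the real workflow, but not: the four-survey temporal design and its seasonal
corrections, building-type mixtures, non-stationarity or anisotropy of the
real radon field, real administrative geography, migration, registry
completeness, or confounder measurement error. Passing recovery tests
demonstrates that the pipeline estimates what it claims under its own
assumptions at desk scale — not that those assumptions hold for any
particular national data set.

## Determinism and problem sizes

Every stochastic stage derives its RNG stream from the run seed through
`numpy.random.SeedSequence` fan-out; per-chain MCMC streams are spawned from
the fit seed. Identical configuration and seed reproduce every artifact byte
for byte. Default desk-scale sizes — 50 × 50 grid, 5,553 survey points,
234 regions, and the reduced sampler protocol used in the examples and the
acceptance script (5 × 4,000 iterations) — were chosen so a complete
pipeline run takes seconds to minutes on a laptop while preserving every
qualitative feature of the full protocol; the full five-chain 20,000-
iteration protocol is the library default for real fits.
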