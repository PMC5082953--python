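# Methods

This note records the model, the conventions and the numerical choices behind
`sagersf`, and what the synthetic data do and do not establish.

## The selection model

Used-available design: telemetry fixes are "used" units; "available" units
are uniform random points over the study extent. Both are buffered by the
season's movement radius and summarized into one covariate vector per disc.
The fitted model is a binomial GLM with logit link and a Gaussian random
intercept per animal,

    logit P(y=1 | x, b_i) = β0 + x'β + b_i,   b_i ~ N(0, σ_b²).

Assumptions worth stating: the intercept β0 is a nuisance of the
used:available sampling ratio (not prevalence); the coefficients β are
interpretable as log selection ratios, exp(β) as odds ratios; locations are
treated as independent given the covariates (no serial autocorrelation or
movement constraint — weekly sampling makes this defensible); and the random
intercept absorbs unequal sampling effort across animals, not
animal-specific selection (slopes are common).

### Random-effect grouping of the availability sample

One seasonal availability pool is shared by all animals. Putting that whole
pool in a single reserved pseudo-group makes every group pure in the
response (each bird contributes only y=1 rows, the pool only y=0), so the
marginal likelihood increases monotonically in σ_b toward a degenerate
optimum (per-group likelihoods → 1/2, loglik → −G·log 2) and the covariates
drop out of the fit. The package therefore defaults to apportioning
available rows uniformly at random (seeded) among the season's animals,
which preserves the single shared pool while keeping σ_b identifiable;
`assign_available_groups(mode="pooled")` retains the degenerate convention
for sensitivity comparisons only. The assignment RNG is salted so that
passing the same integer seed to two different stages can never correlate
the bird labels with the availability draw (an unsalted collision was
observed to fabricate group-level structure, inflate σ̂_b to ~0.6 and bias
all coefficients away from zero).

## Study-design conventions

- Seasons are month–day windows: breeding 1 Apr–15 Jul, summer 16 Jul–1 Sep,
  winter 1 Oct–1 Mar (winter wraps the year boundary and is tracked as one
  episode). Records in the gaps (16–30 Sep, 2–31 Mar) are dropped with a
  logged count.
- The movement radius is the *pooled* mean consecutive-step distance divided
  by the pooled mean step interval (m/day), not the mean of per-step speeds;
  steps whose endpoints fall in different seasons or season episodes are
  excluded. Default radii: 150.8 m breeding, 83.1 m summer, 203.6 m winter.
- Availability sizes default to 7,000 (breeding, winter) and 6,000 (summer).
  `availability_sensitivity` refits a reference model along an N-grid and
  declares convergence at the first N whose maximum per-coefficient relative
  change from the previous N is below 5% (if the very first comparison is
  already stable, the smallest N is credited).

## Covariate operators

- Cell–disc overlap uses exact polygon clipping of square cells against a
  32-gon approximation of the disc (area error < 1e-3 of the circle);
  proportions partition the disc and sum to 1 over all classes.
- Distances are measured from the buffer centroid and are 0 exactly when the
  feature occurs inside the buffer: for raster classes, iff the class has
  positive overlap with the disc; for vector layers, iff point-to-feature
  distance ≤ the radius (the exact circle, so brute-force audits agree to
  machine precision).
- Line density is clipped length ÷ window area (km/km²); for buffers the
  window is the 32-gon disc.
- The energy-development index is the sum of min–max-rescaled active-well
  density and oil/gas-road density, each evaluated over a fixed 1 km²
  axis-aligned window centered on the query point and rescaled over the
  study grid; it ranges over [0, 2], with window area counted in full at
  map edges (outside = development-free). Roads are tagged oil/gas when they
  terminate within 100 m (configurable) of a well pad or intersect a field
  polygon, unless their civil class (highway/county/local) protects them.
  Wells are "active" when status is active and the first recorded milestone
  (spud/completion/first production) predates the study end while the last
  (last production/expiration, else open) postdates its start.
- Vegetation classes covering < 0.1% of the buffered land surface in a
  season are dropped, as are classes absent from every presence buffer (a
  guard against complete separation), each with an audit entry.
- Prediction surfaces use a moving window of the same radius and the same
  operators at every cell center, so training extraction and mapping are one
  operator (verified to ~1e-12 between the two code paths).

## Fitting numerics

- Covariates are standardized internally (mean 0, SD 1 over all rows); the
  optimizer works on the standardized scale and results are mapped back, so
  ill-scaled covariates (elevation in feet) cost nothing. The standardized
  coefficients reported beside the raw ones are the exact reparameterization
  and match an explicit refit on scaled columns.
- Marginal likelihood: adaptive Gauss–Hermite with 21 nodes; per group the
  integrand mode is found by safeguarded Newton steps and the node grid is
  recentered/rescaled there. Agreement with dense trapezoid integration is
  at machine precision on small instances (tested at 1e-4 tolerance).
- Optimization: L-BFGS-B on (β, log σ_b), started from the fixed-effects
  logistic fit (statsmodels) and log σ_b = log 0.3, bounds log σ_b ∈ [−7, 3]
  (the floor is numerically the fixed-effects model; at σ_b = 0 the fit
  matches a plain logistic to < 1e-3). Gradients are analytic (quadrature
  estimate of the score); standard errors come from the finite-difference
  Hessian of that score (observed information), with the σ row dropped when
  σ̂ sits on the floor. Wald intervals use 1.96.
- AICc bookkeeping: k counts the intercept, each fixed effect and the
  variance component; n is the total row count (used + available). These
  conventions are stated so printed AICc values are comparable.
- Complete separation is reported as an error naming the covariates whose
  standardized coefficients exceed 15.
- The 95% confidence set is the smallest weight-ordered prefix whose
  cumulative Akaike weight reaches 0.95 (reaching it exactly qualifies; with
  m equal weights this selects ⌈0.95·m⌉ models).

## Validation

Folds withhold whole birds; by default each of the k=5 folds is an
independent random draw targeting 20% of used rows (greedy add/remove/swap
over a shuffled bird order keeps the realized share within a few points), and
a strict k-way partition mode is available. Available rows remain in every
building set, and the availability sample doubles as the Monte Carlo
estimate of mapped area when binning. Bins are 10 equal-width intervals of
the prediction range (an equal-area quantile option exists); the
area-adjusted frequency of bin i is (n_i/N)/(a_i/A). Spearman r_s is
computed over occupied bins (≥3 required; degenerate folds record NaN), and
AUC is the Mann–Whitney probability that a used row outranks an available
row, ties counted half.

Small withheld samples bias r_s downward: extreme-prediction bins have tiny
areas, so zero withheld counts appear there first and break monotonicity.
With ~50 withheld points per fold r_s sits far below its large-sample value
even for the true model; with ~250+ (the scale of the emulated study) a
well-specified model validates at r_s ≥ 0.9. Test and acceptance problem
sizes were chosen accordingly.

## Energy-development scales

The local scale keeps observations whose buffer disc reaches within 2 km of
an active well (exact circle arithmetic: center distance ≤ 2000 m + radius)
or touches a field polygon. Candidate energy variables are screened against
each other per scale with the drop priority distance-to-oil-roads >
development index > distance-to-wells; the augmented model is compared with
the refitted base model by AICc on the same rows.

`scale_sign_experiment` constructs the mechanism behind a sign flip between
scales: a well field placed at the sagebrush-richest location, a selection
truth containing an unmodeled habitat-quality plateau that is flat within
the local envelope and decays beyond ~3 km, and a genuine road avoidance
saturating at 0.5 km. The linear two-covariate model then yields a negative
distance-to-oil-road coefficient at the landscape scale (good habitat is
where the wells are) and a positive one locally (only the avoidance
remains). The construction is a regression harness for the qualitative
contrast, not an estimate of any real effect size.

## The synthetic generator

What it emulates: a semi-arid basin whose upland mosaic (sagebrush,
sagebrush/grassland, grassland, other) comes from a smoothed Gaussian random
field thresholded to exact class counts; riparian cells hug all streams and
irrigated agriculture hugs a subset of streams only — if agriculture traces
every waterway, distance-to-agriculture duplicates distance-to-water
(r ≈ 0.95) and the pair becomes jointly inestimable, which contradicts the
emulated system where both covariates survived screening. Elevation dips
toward stream valleys; NDVI rises in the irrigated corridors and is designed
to correlate strongly (negatively) with sagebrush at buffer scale, so the
collinearity screen has something real to catch. Wells cluster in compact
fields connected to civil roads by generated access roads; a registry helper
produces mixed statuses and activity dates (defaults 677 wells, 181 active
in the study period).

Telemetry: weekly timestamps with ±2-day jitter spanning April 2010 to
February 2012; per bird a random intercept is drawn and locations are
sampled over grid cells with probability ∝ exp(x'β + b_i), where x is the
cell's moving-window covariate vector at the season's radius. Because a
constant within-bird offset cancels in the softmax, b_i has no spatial
effect — the simulated σ_b exercises the fitting machinery through unequal
per-bird sample sizes (Poisson-dispersed), and parameter recovery targets β
only. Used locations are cell centers (a point-process reading of the RSF;
no movement kernel).

What it does not emulate: telemetry error, serial autocorrelation, nest-site
fidelity, seasonal vegetation dynamics, real hydrology, and any correlation
structure among covariates beyond what the corridor geometry induces.
Passing tests therefore show the *pipeline* is correct under its own model,
not that the model is right for real birds.

### Parameter recovery conditions

`parameter_recovery_experiment` runs one simulate→extract→fit roundtrip: 40
birds × 60 relocations over a year-round window, 6,000 available, on a
200×200 grid of 50 m cells (a 10 km basin). The coarser cell with larger
extent keeps compute constant while giving distance covariates realistic
kilometre-scale ranges — on a 3 km toy map their spread is so small that
their standard errors (≈0.5) exceed any sensible recovery bound, whereas at
10 km the SEs (≈0.06) match the emulated study's printed precision.
Availability is sampled uniformly over grid cells, matching the cell-level
use process exactly. Median absolute errors over replicates sit within
0.15·|β| + 0.1 for every nonzero coefficient.

### The seasonal-workbook stand-in

`make_s1_tables`/`make_s1_workbook` build a workbook with the published
study structure: 1,480/874/1,631 used rows, 117 birds (unequal sampling via
Dirichlet weights), 7,000 shared availability rows, and per-column means
pinned to the printed presence/available values by iterative shift-and-clip.
Marginals are Dirichlet (proportion block, concentration ≈ 2 so the
presence/available distributions overlap broadly, consistent with the
published whole-model AUC of ≈ 0.73), Gaussian elevation and Gamma
distances. Columns are drawn independently: the geometric tie
"distance-to-class = 0 iff proportion > 0" is *not* enforced here (it is
enforced, and tested, in the spatial extractor). Consequently the breeding
top-model AICc on this stand-in (~5,100–5,250) is an emergent number and is
not expected to equal the published value, which depends on the unpublished
raw data; the acceptance script reports it as computed.

## Problem sizes

Routine tests run on 90–120-cell grids with 15–45 birds and availability
samples of 800–4,000; the acceptance script uses 20 recovery replicates,
a 45-bird validation campaign and 3 sign-reversal replicates. These sizes
were chosen so every statistical check has the precision it needs (see the
validation note above) while a full run stays in the minutes range on one
CPU.

## Known limitations

- Two printed coefficient/odds-ratio pairs in the published seasonal tables
  are internally inconsistent beyond rounding (exp(−0.517) ≠ 0.600;
  exp(2.337) = 10.351, printed 10.035 — likely a digit transposition); the
  acceptance checks treat them as printed errata.
- ESRI ASCII grids and GeoJSON carry no CRS; all coordinates are assumed
  projected meters on one shared grid.
- The moving-window prediction operator assumes the training buffers used
  the same radius; mixing radii between training and mapping is not guarded
  against beyond the per-season plumbing.
- The all-subsets fitter is quadratic-cost comfortable up to ~8 screened
  covariates (256 mixed fits); beyond the hard guard of 12 an explicit model
  list is required.
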