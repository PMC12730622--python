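# Methods

This note documents the statistical model, the conventions behind every
numerical choice, what the synthetic data generator does and does not
emulate, and the limitations a user should keep in mind.

## Presence–background design

The model estimates relative habitat suitability by contrasting known
presence locations with randomly placed background points that characterize
the available environment.  Background points are *not* absences: fitted
probabilities are interpretable only up to the unknown sampling intensity,
so maps are read as relative suitability on a 0–1 scale, and thresholds are
defined from the suitability distribution itself (area-based and
presence-retention rules) rather than from a probability calibration.

Class weights normalize presences and background to equal total weight
(0.5 : 0.5).  This makes the null-model intercept logit(0.5) = 0 and keeps
the fit invariant to the background sample size; duplicating background rows
with halved weights provably leaves the fit unchanged (tested).

## Ridge logistic regression

The penalized weighted objective is

f(β₀, β) = −Σ wᵢ[yᵢ log pᵢ + (1−yᵢ) log(1−pᵢ)] + (λ/2)‖β‖₂²,

with the intercept unpenalized and predictors z-scored over the analysis
mask so a single λ penalizes all slopes comparably.

- **Optimizer**: damped Newton (IRLS).  Steps are halved until the objective
  does not increase; convergence when the relative objective change is
  below 1e-9, capped at 200 iterations.  The objective path is asserted
  non-increasing on every fit.
- **λ grid**: 60 log-spaced values spanning 5 decades downward from
  λ_max = max_j |∂NLL/∂β_j at the null model| / 10⁻³.  A pure ridge never
  zeroes slopes exactly, so the lasso-style annihilation point is inflated
  by the conventional 1/α_min factor used by elastic-net software; the top
  of the grid effectively yields the null model.  The penalty is scaled
  against weights summing to 1, so λ values are comparable across runs and
  background sizes (this deliberately does not reproduce any particular
  package's internal rescaling).
- **λ selection**: stratified-by-class internal CV with
  k = min(5, n_presence) folds, minimizing mean held-out weighted deviance
  (no one-standard-error rule).  With a single presence no internal CV is
  possible and a fixed λ must be supplied.  Warm starts along the grid give
  a slope-norm path that is asserted non-increasing in λ.
- **Small-sample behaviour**: at n_presence = 6 (the motivating case) the
  internal CV frequently selects very strong shrinkage, leaving coefficients
  near zero and the suitability surface close to 0.5 everywhere.  This is
  the statistically honest answer for six points — the worked example in
  the README uses 30 presences to show non-degenerate structure.

Alternative presence-background learners (Maxent-style models, bias-reduced
GLMs) are deliberately out of scope; an unpenalized weighted GLM is the
λ = 0 member of the family and serves as the oracle cross-check in the test
suite (verified against an independent scipy optimizer to 1e-6).

## Synthetic landscapes

The generator produces the statistical structure the analysis assumes, not
geographic realism:

- **Elevation**: Gaussian-filtered white noise (σ = 8 cells by default)
  rescaled to 200–1600 m on a 128×128 grid of 90 m cells — smooth,
  ridge-bearing topography at the analysis resolution of the motivating
  study.
- **Climate**: temperature is an affine lapse of elevation
  (14 °C at sea level, 6.5 °C/km) plus Gaussian noise (sd 0.3 °C);
  tmax = tmean + |6 °C + noise| so tmax ≥ tmean holds everywhere;
  precipitation and relative humidity increase orographically
  (1100 mm + 0.35 mm/m; 62% + 0.008 %/m) with noise, clipped to their
  physical ranges.
- **Soils**: sand/silt/clay are a softmax of three smooth logit fields
  (closure to 100% holds to machine precision); CEC and SOC are lognormal
  transforms of smooth fields, hence non-negative.
- **Limestone**: a second smooth field thresholded at the quantile giving
  the target areal fraction (default 0.3) — contiguous blobs, not
  salt-and-pepper noise.
- **Occurrences**: distinct cells drawn without replacement with probability
  proportional to expit(β₀ + Σ βⱼ zⱼ), where zⱼ are predictors z-scored over
  the limestone mask; one presence per cell, placed at cell centres (the
  motivating data are one point per site; georeferencing precision is a
  design decision, not an inference).
- **Daily climate**: sinusoidal seasonal cycles with Gaussian daily noise;
  precipitation is Bernoulli–gamma (dry-day probability 0.6, gamma shape
  0.9, scale 12 mm — a realistic mid-latitude monsoon regime of ~1400 mm/yr).
  Biased "raw" series are the reference shifted additively (temperature,
  RH) or scaled multiplicatively on wet days (precipitation).

What the generator does **not** emulate: spatial autocorrelation in the
noise fields beyond smoothing, anisotropy, survey bias in occurrence
detection, coordinate error, and real geological structure.  Passing tests
therefore demonstrate the correctness of the algorithms under the assumed
data model, not predictive performance on real rasters.

**Study conditions for the simulation experiments.**  Sign recovery uses
generative slopes (+2, −2, 0) on three weakly correlated predictors at 300
presences.  The recoverable-signal spatial-CV experiment uses a
low-prevalence species (generative intercept −6 with strong slopes
3/−3/2): a rare, narrowly distributed species concentrates its presences in
a small high-suitability area, which is both the ecologically relevant
regime for relict-species modelling and the regime where spatial folds
retain discriminable signal.  At high prevalence (intercept near 0) the
logistic surface saturates and the attainable AUC ceiling drops — a property
of the generative design, not of the estimator.

## Raster conventions

- Row 0 is the northernmost row; cells are half-open [edge, edge); points
  map to cells by floor((x − origin)/cell_size).  In memory nodata is NaN;
  on disk it is the grid's sentinel in ESRI ASCII files.
- **Alignment**: continuous layers bilinear, categorical nearest-neighbour;
  any nodata contributor poisons the output cell; a layer already on the
  target grid passes through bit-identically.  Bilinear interpolation is
  exact on affine fields (tested against the closed form).
- **Slope/aspect**: Horn's 8-neighbour weighted differences, the convention
  of mainstream GIS raster engines.  Aspect is the downslope direction,
  degrees clockwise from north.  Flat cells have undefined aspect (nodata)
  but (0, 0) eastness/northness so they remain usable predictors.
- **TRI**: mean absolute difference to the 8 neighbours (the convention of
  the R terra engine); a root-sum-of-squares variant is available via
  `variant="rss"`.
- **TPI**: cell minus the mean over a circular window of cells whose centres
  lie within the radius (centre excluded), radius in metres; windows are
  clipped at the raster edge rather than padded.
- **Standardization**: means/sds computed over the analysis-mask cells (not
  the full domain) and applied identically to map cells and point
  extractions; zero-variance layers raise an error naming the layer.

## Climate bias correction

Empirical quantile mapping with 99 equally spaced probability knots
(p = k/100).  Additive mode (temperature, RH) interpolates the correction
Q_ref − Q_raw linearly between knots; multiplicative mode (precipitation)
interpolates the ratio Q_ref/Q_raw and applies it only to wet days
(> 0.1 mm), so the dry-day count is preserved exactly.  Beyond the outermost
knots the edge correction is held constant — standard practice when the
correction must extrapolate.  Climatologies average complete years only; a
year passes quality control when ≥ 95% of its days are present and finite.
"Annual maximum temperature" is resolved as the mean over years of each
year's maximum daily tmax (a deliberate choice between that reading and the
single multi-year maximum).

## Masking and sampling

- The elevation band is percentile(occurrence elevations, 5)−100 m to
  percentile(…, 95)+200 m with linear interpolation between order
  statistics (numpy's default); the convention is switchable because small
  samples make band endpoints sensitive to it.  Occurrence elevations come
  from DEM extraction at occurrence cells (a config option allows
  field-recorded altitudes instead).
- The collinearity filter drops, at each iteration, from the currently worst
  offending pair the non-protected variable with more offending partners
  (ties: the later one in input order), recomputing until no |ρ| > 0.7
  remains.  Two protected predictors exceeding the threshold with each other
  are both kept with a warning.  In the pipeline the Spearman matrix is
  computed over the analysis-mask cells, since filtering precedes background
  sampling.
- Background sampling is uniform within stratum: round(0.3 n) cells from the
  mask∩3 km-buffer stratum, the remainder from the whole mask; without
  replacement when enough cells are eligible, otherwise with replacement and
  a warning (small synthetic masks routinely have fewer than 5000 eligible
  cells).  Background may coincide with presence cells — this is a
  presence–background design.
- Rows with any nodata predictor are dropped at extraction with a logged
  count (edge cells lack terrain derivatives), after which class weights are
  computed from the surviving counts.

## Thresholding and evaluation

- Score comparisons use ≥ (ties classified positive) throughout; TSS at tied
  scores depends on this and it is stated once here.
- Candidate thresholds are the midpoints between adjacent distinct pooled
  scores, the scores themselves, and sentinels below/above; Youden maximizes
  TSS, spec-sens minimizes |sensitivity − specificity|; ties return the
  lowest candidate.
- The final threshold rule is min(upper-decile, P10) by default.  A
  strict-MTP rule (min(upper-decile, MTP), guaranteeing 100% presence
  coverage) and a top-decile-only rule are configurable: full-coverage
  correction rules and sub-100% observed coverage cannot hold
  simultaneously, so both behaviours are exposed and the chosen rule is
  echoed in every report.
- Spatial CV clusters all presence and background coordinates with seeded
  k-means (10 restarts); per fold the model is refitted on the training rows
  with weights renormalized to 0.5 : 0.5 within the subset.  Folds whose
  training subset cannot support a refit are recorded as undefined with a
  note; test folds with fewer than 2 presences are flagged sparse.  Summary
  statistics are the mean, sample SD (n−1) and median over defined folds;
  with very few folds the median is the more robust summary.

## Pipeline and problem sizes

The pipeline composes simulate → prepare → mask → filter → sample → fit →
predict → threshold → cv → report, with all randomness drawn from five named
stage seeds; two runs of one config produce byte-identical artifacts
(checksummed manifest).  The default synthetic grid is 128×128 at 90 m; the
acceptance script uses 48×48 grids for the determinism check, 20 seeded
128×128 landscapes for sign recovery, and 5 for the spatial-CV experiments —
sizes chosen so the full recomputation stays interactive while keeping every
Monte-Carlo margin comfortable.

## Known limitations

- No reprojection engine: all layers must share a projected CRS in metres.
- Linear logits only — no spline/hinge/product features, no spatial
  autocorrelation terms, no calibration metrics (e.g. Boyce index).
- Quantile mapping is unstratified by season and fitted per series; the
  multiplicative transfer interpolates the ratio, which is monotone for the
  smooth quantile functions encountered here but is not guaranteed monotone
  for adversarial quantile pairs.
- The synthetic generator's simplifications listed above mean real-data
  performance claims require real rasters and occurrences.
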