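# Methods

This note documents the statistical model, the synthetic data-generating
process, the numerical choices, and the known limits of what the test suite
demonstrates.

## Model and estimation

The response (weekly NO or NO₂ in µg/m³ at a monitoring site) is modelled as

y_ij = α₀ + β₁ X_i + β₂ Met_j + β₃ Month(j) + b_i + γ_j + ε_ij,

with independent Normal random intercepts b_i (site) and γ_j (week) and iid
residuals. Sites and weeks are *crossed*, not nested: rotating sites share
weeks with the fixed sites, which is what identifies σ²_week separately from
σ²_site. Continuous predictors are standardized (training mean/SD, sample SD
with ddof = 1), so coefficients are per-SD effects in µg/m³; month dummies
are left untouched, with the earliest observed year-month as the reference
level (configurable). The calendar month of an ISO week is the month
containing its Thursday — every week then belongs to exactly one month.

Estimation maximises the REML criterion profiled over the two variance
ratios θ_k = σ²_k/σ²_resid. Writing V₀ = I + θ_s Z_s Z_sᵀ + θ_w Z_w Z_wᵀ,
GLS coefficients, the profiled residual variance σ̂² = rᵀV₀⁻¹r/(n−p) and the
criterion

−2ℓ_R = (n−p)(1 + log 2πσ̂²) + log|V₀| + log|XᵀV₀⁻¹X|

are closed-form in θ. All solves route through the q×q capacitance matrix
M = UᵀU + D⁻¹ (U = [Z_s | Z_w], q = n_sites + n_weeks), with the
cross-products UᵀU, UᵀX, Uᵀy, XᵀX cached at construction, so one criterion
evaluation costs O(q³) after an O(n q²) setup; instances with n = 5000 fit in
well under a second. The two-dimensional search runs Nelder–Mead in log-θ
from three starts (the surface is smooth and, in our experience, unimodal;
the extra starts guard against a boundary basin), with xatol 1e−10 on log-θ.
Ratios that converge below e⁻²⁰ are reported as structural zeros, so the
degenerate no-random-effect fit reproduces OLS exactly. BLUPs are
b̂ = θ_s Z_sᵀ V₀⁻¹ (y − Xβ̂) and likewise for weeks; the standard errors of β̂
come from σ̂² (XᵀV₀⁻¹X)⁻¹.

The R² decomposition is the variance-ratio form for mixed models: with
var_f the sample variance of the fixed-effects linear predictor,
R²_fixed = var_f / (var_f + σ²_site + σ²_week + σ²_resid) and R²_mixed adds
the two intercept variances to the numerator. By construction
R²_fixed ≤ R²_mixed.

Prediction at a new location uses the population-level site effect
(b = 0); the week intercept is added whenever the week was in the training
data, which is the relevant case for mapping campaign weeks. Months never
observed in training fall back to the reference level and are flagged.

## Variable selection

The selection stage reproduces the supervised LUR recipe with every choice
made explicit:

- **Buffer choice**: for each buffered variable, the radius maximising
  |Pearson r| with the response; ties break toward the smaller radius;
  |r| < 0.1 is flagged (not dropped); zero-variance or non-finite variables
  (e.g. the +∞ road-distance sentinel when a class is absent) are dropped
  with a warning. One buffer per variable enters the pool.
- **Forward stepwise**: candidates are ranked by OLS adjusted R² of the model
  including them; the best-ranked candidate is retained only if its fitted
  sign matches the declared a-priori direction and the adjusted-R² gain is
  ≥ 1 absolute percentage point (the conventional reading of a "1% gain"
  rule). A sign-violating top candidate is rejected permanently and the next
  tried; once the best available gain drops below the threshold, selection
  stops. Adjusted R² is computed from OLS on the fixed-effects design rather
  than from a REML refit per candidate — adjusted R² is an OLS notion, and
  the mixed model is fit once, after selection. (A switch to score candidates
  on the mixed fit is deliberately not offered; the OLS screen is the
  documented behaviour.) Spatial and meteorological candidates compete in
  the same pool; the acceptance order is recorded in a replayable trace.
- **Collinearity**: VIF_k = 1/(1−R²_k) from regressing column k on the
  others; columns with VIF > 3 are removed one at a time, largest first,
  right-most on ties (so the later-added of a perfectly collinear pair is
  the one removed), then the model is refit.

## Synthetic city

The generator emulates the layers and the sampling design the analysis
assumes, on a local metric plane (buffer radii are metres, so a projected
CRS is mandatory):

- **Layout**: a monocentric city — commercial core, high-density ring,
  low-density suburbs, peri-urban fringe; major roads as long chords through
  the centre region, shorter secondary segments; NDVI rising with distance
  from the core; POIs clustered in the core; enumeration areas as an
  irregular rectangular tiling that partitions the extent exactly, with
  population density decaying outward, biomass share higher centrally, and
  SES (median log equivalized household consumption, centre 8.0, gradient
  +1.0 outward, noise SD 0.15) increasing outward. This plants the
  structure the equity stage is meant to detect: central EAs are poorer and
  more exposed.
- **Campaign**: 10 fixed sites measured every one of 52 weeks plus 124
  rotating sites measured one week each (644 scheduled records per
  pollutant), sites over-represented in the dense core; optional uniform
  record drop-out (default 0) emulates campaign gaps.
- **Meteorology**: two-regime weekly series starting April 2019 — Harmattan
  (Nov–Feb) with lower wind speed (1.8 vs 3.2 m/s), fewer rain days, lower
  RH, shallower mixing; transitional March–April weeks at the regime
  midpoint. Rain days are Binomial(7, p) per week.
- **Concentrations**: NO₂ and NO are simulated as separate responses from
  the mixed model above, sharing spatial predictors but with independent
  random draws (their error dependence is not modelled). Default truth
  coefficients mirror a fitted urban NOₓ model on the standardized scale:
  for NO₂, intercept 40.1, major-road length (100 m) +5.6, secondary-road
  length (200 m) +10.4, NDVI (50 m) −13.7, wind −11.0, RH −4.1, month
  effects up to ≈29; for NO, intercept 61.8, major-road +23.4,
  secondary-road (50 m) +15.8, bars (500 m) +3.3, solar −4.0. Random-effect
  SDs (NO₂: 12/8/10; NO: 10/9/17 for site/week/residual) were chosen so the
  fixed and mixed R² land near the 0.6 / 0.8–0.9 regime typical of such
  models. Concentrations are floored at 0 after noise (physical
  non-negativity); NOₓ = NO₂ + NO, so NOₓ ≥ NO₂ record-wise by
  construction. All random draws (site effects, week effects, linear
  predictors, standardization parameters) are logged for recovery tests.

What the generator does *not* emulate: spatial autocorrelation of residuals
beyond the site intercept, temporally autocorrelated meteorology, measurement
blank/duplicate error structure, NO→NO₂ chemistry (the seasonal contrast is
purely statistical, via coefficients), and non-rectangular EA shapes.
Passing tests therefore show the pipeline recovers its own assumed model
class under a realistic design — not that the model class is right for any
particular real city.

## Units

ppb → µg/m³ conversion uses conc × MW / V_m with MW(NO₂) = 46.0055,
MW(NO) = 30.006 g/mol and V_m the ideal-gas molar volume at the given
temperature and pressure (default 1013.25 hPa); at 25 °C this yields the
familiar 1.88 and 1.23 factors. NO is derived from NOₓ − NO₂ in ppb before
mass conversion (mass units are not closed under that subtraction); negative
differences are clipped to 0 and flagged. A humidity-correction hook exists
but is an identity by default: the sampler-specific role of RH in the
conversion is not standardised, so none is imposed.

## Validation, surfaces, equity

Cross-validation assigns *records* (not sites) to 10 seeded folds of
near-equal size, refits the mixed model per fold with the predictor set
frozen (CV evaluates the final model, not the search), and predicts held-out
records with the site intercept zeroed — the "unmonitored location" view —
while reusing training week intercepts. Metrics: RMSE, MAE, and R² as the
squared Pearson correlation between predicted and measured, pooled over all
held-out predictions and reported per fold.

Surfaces are predicted at grid-cell centres (default 50 m; partial edge
cells included and flagged), spatial features extracted once per cell and
reused across weeks and models. Weekly layers are floored at 0 for mapping
with raw values retained. Season aggregates are unweighted cell-wise means:
annual over all predicted weeks, Harmattan over Nov–Feb, non-Harmattan over
May–Oct; transitional Mar–Apr weeks enter the annual mean only.

EA exposure is the unweighted mean of cells whose centres fall in the EA
polygon (cells are equal-area); EAs capturing no centre fall back to their
centroid value, flagged. The population CDF reports the population share at
or below thresholds — by default multiples 1×–8× of the WHO annual NO₂
guideline (10 µg/m³) plus the former 40 µg/m³ guideline. SES quintiles use
the rank-percentile rule (quintile of 0-based rank i among n is
⌊5i/n⌋ + 1; stable order on ties), so sizes differ by at most one EA. The
extreme-quintile contrast is a Welch (unequal-variance) two-sample t-test
with a 95% CI; two degenerate equal-mean zero-variance groups return p = 1.

## Problem sizes and determinism

The bundled end-to-end runs use a 6 km × 6 km city (144 EAs, 52 weeks,
10 + 124 sites, 644 records per pollutant); the prediction grid coarsens
from 50 m toward ≤10⁴ cells for the mapping stage, a cap chosen to keep the
full pipeline around a minute on one CPU while leaving the statistical
stages at full size. Every stage is seeded: identical (seed, configuration)
reproduces identical outputs bit-for-bit, and pipeline stage seeds are
derived from a single master seed.

## Known limitations

- The REML optimiser is derivative-free; with more than two variance
  components a gradient-based profile would be preferable.
- No spatial residual correlation (kriging) and no temporal autoregression;
  the week intercept absorbs purely shared temporal shocks.
- Prediction-interval surfaces are not produced, only point predictions.
- CV is record-level; leave-site-out or spatially blocked CV would give a
  sterner test of spatial generalisation and is a natural extension.
- Shapefile/GeoTIFF I/O is not supported; vector layers are GeoJSON and
  rasters ESRI ASCII grids.
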