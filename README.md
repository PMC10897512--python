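# citynox

Spatiotemporal land-use regression (LUR) for weekly **NO** and **NO₂**
concentrations in a city, built for monitoring campaigns that mix a few
long-running *fixed* sites with many one-week *rotating* sites — the design
used to map traffic-related air pollution in rapidly growing cities where no
regulatory monitoring network exists.

## Who this is for

Exposure scientists and environmental epidemiologists who have (or plan) a
passive-sampler NOₓ/NO₂ campaign plus standard GIS layers (roads, land use,
NDVI, points of interest, census enumeration areas) and want city-wide weekly
concentration surfaces, their seasonal summaries, and population /
socioeconomic exposure distributions. A seeded synthetic-city generator
reproduces the whole data-generating process, so every stage of the pipeline
can be exercised and tested without any external data.

## The model

Weekly concentration at site *i* in week *j* is modelled as a linear mixed
model with **crossed random intercepts** for site and week:

```
y_ij = α₀ + β₁·X_i + β₂·Met_j + β₃·Month(j) + b_i + γ_j + ε_ij

b_i ~ N(0, σ²_site),   γ_j ~ N(0, σ²_week),   ε_ij ~ N(0, σ²_resid)
```

- `X_i` — buffered spatial predictors (road length, land-use area, NDVI, POI
  counts, population density, biomass share within 50/100/200/500 m buffers,
  plus distances to the nearest major/secondary road), standardized.
- `Met_j` — weekly meteorology (temperature, RH, wind speed, mixing-layer
  depth, solar radiation, water-vapour mixing ratio, rain days), standardized.
- `Month(j)` — calendar-month fixed effects (month of the ISO week's
  Thursday), dummy-coded against the earliest observed month.

Estimation is REML, profiled over the two variance ratios with low-rank
(Woodbury) covariance solves. Predictor sets are chosen by the supervised
LUR recipe: per-variable buffer choice by |Pearson r|, sign-constrained
forward stepwise with a 1-percentage-point adjusted-R² gain rule, then
iterative removal of variables with VIF > 3. Model skill is assessed by
10-fold cross-validation (RMSE, MAE, and R² between predicted and measured,
with held-out sites treated as unmonitored locations). Fitted models are
evaluated on a 50 m grid for every campaign week; weekly layers are averaged
into annual, Harmattan (Nov–Feb) and non-Harmattan (May–Oct) surfaces, then
overlaid on enumeration areas to yield population exposure distributions
versus the WHO annual NO₂ guideline (10 µg/m³) and a Welch contrast of mean
exposure between the poorest and wealthiest SES quintiles.

Species/unit arithmetic: NO = NOₓ − NO₂ in ppb (clipped at 0), then converted
to µg/m³ with the ideal-gas molar volume — at 25 °C / 1013.25 hPa, 1 ppb NO₂
≈ 1.88 µg/m³ and 1 ppb NO ≈ 1.23 µg/m³.

## Worked example

```python
from citynox.pipeline import run_pipeline

result = run_pipeline(seed=1)           # 6 km x 6 km synthetic city,
                                        # 10 fixed + 124 rotating sites, 52 weeks
r2_fixed, r2_mixed = result.no2.fit.r2()
print(f"NO2 R2 fixed={r2_fixed:.2f} mixed={r2_mixed:.2f}")
print(f"NO2 CV: R2={result.no2.cv.r2_cv:.2f} RMSE={result.no2.cv.rmse:.1f} "
      f"MAE={result.no2.cv.mae:.1f}")
print(result.season_summary.round(1))
c = result.contrast
print(f"poorest vs wealthiest quintile: {c.mean_low_ses:.0f} vs "
      f"{c.mean_high_ses:.0f} ug/m3 (p={c.p_value:.1e})")
```

prints (seed 1):

```
NO2 R2 fixed=0.62 mixed=0.91
NO2 CV: R2=0.78 RMSE=16.1 MAE=12.8
               n_weeks  mean    sd  min    max
layer
annual              52  49.6  15.9  3.0   97.7
harmattan           17  71.3  16.4  9.3  119.6
non_harmattan       27  39.5  15.7  0.0   87.6
poorest vs wealthiest quintile: 66 vs 36 ug/m3 (p=3.4e-13)
```

Reading this: the fixed effects alone explain 62% of the spatiotemporal
variance and the full mixed model 91%; cross-validated skill at unmonitored
locations is R² = 0.78 with errors small against the 0–190 µg/m³ range of the
simulated city. NO₂ is highest in the dusty Harmattan season, and the
poorest fifth of enumeration areas is ~30 µg/m³ more exposed than the
wealthiest — the exposure-inequality pattern the synthetic city is built to
exhibit.

Lower-level use follows the statsmodels convention:

```python
from citynox import CrossedLMM
model = CrossedLMM.from_dataframe(df, "no2",
                                  ["major_road_length_100", "ndvi_50", "wind_speed"])
res = model.fit()
print(res.summary())
pred = res.predict(new_rows, iso_week="2019-W45")   # unknown site => b_i = 0
```

A `citynox` CLI exposes the stages (`simulate`, `extract`, `select`, `fit`,
`cv`, `predict`, `equity`) over text formats: GeoJSON vectors, ESRI ASCII
grid rasters, CSV tables and YAML models.

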