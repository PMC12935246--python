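# Methods

This note documents the models implemented in `droughtnpp`, the choices made
where the methodology was genuinely open, the synthetic scenario the test
suite runs on, and what the package does and does not demonstrate.

## Grid contract

All rasters live on one explicit grid (`GridMeta`): north-up, origin at the
outer corner of the top-left cell, explicit nodata sentinel. Two rasters are
combinable if and only if every metadata field matches; nothing resamples
implicitly. A nearest/bilinear utility (`grids.resample_field`) exists for
pre-aligning external inputs, and the caller must invoke it deliberately —
silent regridding is the commonest source of irreproducible raster
statistics. Time is a list of `(year, month)` pairs, strictly monthly and
gap-free; a missing month is a hard error naming the gap. Persistence is
single/multi-band TIFF (grid metadata as JSON in the ImageDescription tag)
or NetCDF3 via xarray's scipy backend; both round-trip bit-identically,
which is what makes pipeline manifests checksum-reproducible.

## Thornthwaite PET

PET needs only temperature and latitude here. The heat index
`I = Σ (T̄_m/5)^1.514` is built from each pixel's multi-year mean
temperature of the calendar months with a positive mean; the exponent is the
standard cubic in `I`; `PET = 16 (10T/I)^a` mm/month, scaled by day length
(solar declination at mid-month; valid only for |lat| ≤ 66.5°, enforced)
and month length. Months at or below 0 °C evaporate nothing. Thornthwaite
was chosen over Penman-type formulations because it is the minimal-input
standard companion of SPEI; it is a documented dialect switch-point, not a
claim that alternative PET models would give identical indices.

## SPEI

For scale k, the k-month running sum of `D = P − PET` (window valid only if
every member month is) is standardised per pixel *and calendar month* over
the full record (the fit reference period). Each stratum series — typically
20 values for a 20-year record — is fitted with a three-parameter
log-logistic distribution via L-moments from unbiased probability-weighted
moments, in the generalized-logistic parameterisation (shape κ = −τ₃): the
same family, but it extends smoothly to negatively L-skewed strata, which
are common once k-month sums become near-symmetric. The fitted cumulative
probability is clipped to [1e−6, 1−1e−6] and mapped to a standard normal
deviate with the classical rational inverse-normal approximation
(c₀ = 2.515517, c₁ = 0.802853, c₂ = 0.010328, d₁ = 1.432788, d₂ = 0.189269,
d₃ = 0.001308). Degenerate strata (no spread beyond rounding, incomplete
series, |τ₃| ≥ 0.95) are masked and counted in the log, never silently
zero-filled; the first k−1 steps are masked by construction.

Calibration, verified by the suite on gamma-simulated precipitation
(500 pixels × 240 months): per-stratum mean within ±0.15, SD within
[0.85, 1.15], ranks preserved in every stratum. The monotone-transform
property means the index is insensitive to the exact distribution family as
far as ordering is concerned; the family matters only for the tails.

## SSMI

The k-month running mean of soil moisture, standardised as a z-score. The
standardisation population is the calendar-month stratum by default — the
reference formula ("multi-year mean and SD at that identical scale") is
ambiguous between calendar-month and whole-series grouping; calendar-month
was chosen so the index is an anomaly against the seasonal norm, and
`stratify="whole_series"` is offered. Population SD (ddof = 0) makes the
stratum mean and SD exactly 0 and 1 over the record, which the tests assert
to 1e−12. A stratum whose spread is at rounding-noise level (relative
tolerance 1e−10) is masked as degenerate rather than standardised into ±1
artifacts.

## Severity grades, drought frequency, aridity

Severity follows the SPEI and SSMI grading tables used in Chinese drought
monitoring, boundaries closed on the dry side: under SPEI, no-drought
extends down to −0.5, mild (−1, −0.5], moderate (−1.5, −1],
severe (−2, −1.5], extreme ≤ −2; under SSMI any non-positive value is
already at least mild drought. `DFI = 100·m/M` counts months at or below a
threshold; the default threshold is −1 (the "drought has occurred"
convention), with a config override to −0.5 since drought-area analyses
usually count mild droughts too — the discrepancy between the two
conventions is surfaced in configuration rather than hidden. Aridity
classes use half-open intervals at 1, 1.5 and 4.

## CASA NPP

`NPP = APAR × ε`, `APAR = 0.5·SOL·FPAR`, `ε = T₁·T₂·W·ε_max(class)`.
The published core of the model is the two equations above; the stress
scalars and FPAR construction follow the widely used modified-CASA lineage
and every constant is exposed in `CasaParams`:

* **FPAR** — mean (α = 0.5) of the NDVI linear ramp and the simple-ratio
  ramp (`SR = (1+NDVI)/(1−NDVI)`, NDVI clamped to ≤ 0.99), each scaled
  between FPAR bounds (0.001, 0.95). Class NDVI bounds default to the
  5th/95th percentiles of that class's record — robust to outliers and
  self-calibrating on any input.
* **T₁** = 0.8 + 0.02·T_opt − 0.0005·T_opt²; **T₂** =
  1.1814 / (1+exp(0.2(T_opt−10−T))) / (1+exp(0.3(−T_opt−10+T))). T_opt is
  the multi-year mean temperature of the calendar month with maximal mean
  NDVI; ties break to the earliest month (determinism).
* **W** = 0.5 + 0.5·EET/PET, with EET from the regional
  precipitation/net-radiation coupling
  `EET = P·Rn·(P²+Rn²+P·Rn)/((P+Rn)(P²+Rn²))` and the proxy
  `Rn ≈ 0.369·PET + 0.598·P`. The default mode is precipitation-based
  because the canonical model inputs are rainfall, temperature, sunshine,
  NDVI and land use — no soil moisture; a soil-moisture mode
  (`W = 0.5 + 0.5·SM/SM_p95`) is provided for sensitivity analysis.
* **ε_max** defaults (gC/MJ): farmland 0.542, grassland 0.542,
  woodland 0.692. These are calibration constants from the modified-CASA
  literature, flagged as assumptions, and configurable.

Non-vegetated classes (water, construction, ice/bare) are masked, never
zero-filled into statistics. Annual NPP is the 12-month sum, masked if any
month is masked. A benchmark regression of class-by-year mean annual NPP
against a reference cube reports slope/R²/p; on self-consistent input
R² = 1 exactly, which the pipeline uses as an internal consistency check
when no external reference cube is supplied.

## Trend and association statistics

Sen slope = median of all pairwise slopes; Mann-Kendall S with
tie-corrected variance and continuity correction, two-sided normal p.
Per-pixel trends use calendar-year aggregates (sums for NPP/precipitation,
means for temperature and indices) so slopes are in per-annum units; this
is also why the per-pixel record is only n = 20 — significance classes at
α = 0.05 should be read accordingly. The type-I error of the implementation
is verified by simulation to sit in [0.03, 0.07] at n = 20.

Pearson correlations are annual (NPP sums vs precipitation/radiation sums
and temperature means); p from the t transform with df = n−2. Partial
correlations invert the joint correlation matrix
(`r_ij·c = −Ω_ij/√(Ω_ii Ω_jj)`, df = n−2−#controls); constant controls are
dropped per pixel (degenerating gracefully to plain Pearson), singular
matrices mask the pixel. Drought-index correlations align windows with
scale: the 3-month index at a season's final month (May, Aug, Nov, Feb —
December belongs to the following year's winter) represents that season,
the 12-month index at December represents the year, 1-month indices pair
with monthly NPP. Correlations are computed per pixel over years — the only
construction consistent with mapped correlation fields. No multiple-testing
correction is applied to area fractions of p < α, matching common practice
in this literature; the fractions are descriptive, not inferential.

## ΔNPP impact tables and skill validation

The baseline for (class, calendar month) is the mean NPP over all pixels of
the class and all years where that month's severity is "none" — pooled over
space because per-pixel baselines are far too noisy at n ≈ 20 per cell.
Drought pixel-months contribute `100·(NPP − baseline)/baseline`, aggregated
by class × severity (× month) as n-weighted means; cells with no
contributing samples are absent rather than zero, and zero baselines are
excluded with a logged count. The early-vs-peak season comparison contrasts
Mar–May and Jun–Aug window means per class × severity. The default severity
source is the 1-month index (configurable) — the monthly ΔNPP stratification
needs a monthly-resolution severity label.

Skill validation needs a monthly regional drought flag that event catalogs
never define, so both obvious rules are implemented: regional mean index
≤ τ (default −0.5) or area fraction at ≥ mild ≥ φ (default 0.3).
Contingency counting is month-level (hits = flagged event months,
misses = unflagged event months, false alarms = flagged non-event months),
chosen over event-level counting because it is deterministic and auditable;
POD = H/(H+M), FAR = F/(H+F), CSI = H/(H+M+F), with scores absent (not 0)
when a denominator is empty.

## Synthetic scenario

The generator emulates a 20-year (2001–2020, 240-month) monthly record on a
default 40×40 grid — the spatial extent is a desk-scale design choice; the
temporal span and climate statistics are the study conditions:

* temperature: annual mean 10.74 °C, seasonal amplitude 14 °C (July peak),
  trend +0.02 °C/a, white noise SD 1 °C;
* precipitation: annual total 580.52 mm rising 2.65 mm/a, split by a
  summer-monsoon monthly weight vector (July ≈ 23%), monthly totals gamma
  with shape 2;
* solar radiation: 450 ± 230 MJ m⁻² month⁻¹ seasonal cycle;
* soil moisture: leaky bucket
  `SM_t = clip((1−λ)SM_{t−1} + β·P_t − γ·PET_t, 0, cap)` with λ = 0.3,
  β = 0.002 /mm, γ = 0.001 /mm, cap = 0.45, PET the package's own
  Thornthwaite output — this physical coupling is what makes SSMI and SPEI
  strongly positively correlated downstream without extra machinery;
  a 60-month spin-up on the first-year forcing removes initial-condition
  transients;
* NDVI: per-class logistic of the standardised 3-month precipitation
  anomaly on top of a seasonal cycle, clipped to [0.01, 0.95]; default
  sensitivities grassland 1.2 > farmland 0.6 > woodland 0.3 (grasslands
  most drought-synchronous, woodlands buffered), ≈ 0.02 for
  water/construction/ice;
* land cover: a 2×3 block mosaic of the six classes;
* drought episodes: a default calendar of six multi-month events
  (spring 2004; spring–summer 2005; Nov 2008–Aug 2009; Jun–Nov 2010;
  Dec 2013–Aug 2014; Oct 2017–Mar 2018) multiplying precipitation by
  (1 − deficit) with deficits of 0.40–0.50, reported back as the event
  catalog the skill validation is scored against.

Noise is spatially white by default so pixels are independent samples for
the per-pixel statistics. What the generator does *not* emulate: weather
autocorrelation beyond the bucket recursion, spatially correlated climate
fields, topographic gradients, land-cover change over time, or
anthropogenic NPP signals (irrigation, land conversion). Passing tests
therefore demonstrate that the estimators recover structure they are
pointed at under clean conditions — not that the pipeline's outputs on real
rasters carry the same precision.

Two dedicated validation scenarios live beside the generator:
`confounded_temperature` (temperature as a noisy copy of the precipitation
anomaly, used to show partial correlation removes a confounder) and
`npp_drought_scenario` (an NPP cube with known fractional reductions per
class × severity — grassland severe = 30% — used to show the ΔNPP tables
recover imposed impacts, to within the small positive bias that
multiplicative noise in the non-drought baseline contributes).

## Numerical choices

* Probabilities clipped to [1e−6, 1−1e−6] before the inverse-normal map
  (|z| ≤ 4.76); the rational approximation's absolute error is < 4.5e−4.
* NDVI clamped to ≤ 0.99 before the simple ratio (SR diverges at 1).
* All masks propagate; any statistic over an empty valid set is absent or
  NaN, never 0.
* Checksummed manifests: identical config + seed reproduce every artifact
  byte-for-byte (TIFF writes carry no timestamps; NetCDF3 is deterministic).
* Default sizes keep a full pipeline run and the whole validation suite in
  the seconds-to-a-minute range on one CPU.

## Known limitations

* Thornthwaite PET underestimates demand in windy/advective climates; the
  SPEI dialect is therefore not identical to products built on Penman-type
  PET.
* ε_max and the stress-scalar constants are literature defaults, not
  region-calibrated values; absolute NPP levels should be treated as
  relative until calibrated.
* n = 20 annual samples bound the power of per-pixel trend and correlation
  tests; area fractions of significant pixels are descriptive.
* Month-level skill counting weights long events more than event-level
  counting would; the two are not interchangeable when comparing against
  published scores.
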