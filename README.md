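# droughtnpp

Gridded analysis of drought and its impact on vegetation net primary
productivity (NPP), for monthly raster records of the kind produced by
regional remote-sensing studies: precipitation, air temperature, solar
radiation, surface soil moisture, NDVI and a static land-cover map on a
shared grid, 2001–2020 style.

It is aimed at ecohydrologists and carbon-cycle analysts who want the full
chain — drought indices, light-use-efficiency NPP, trend fields, driver
correlations, drought-impact tables and event-catalog validation — as one
reproducible, scriptable pipeline instead of a GIS workflow.

## What it computes

**NPP (CASA light-use-efficiency model).** Monthly
`NPP(x,t) = APAR(x,t) × ε(x,t)` with `APAR = 0.5·SOL·FPAR` and
`ε = T₁·T₂·W·ε_max`. FPAR comes from NDVI (mixed linear-ramp /
simple-ratio estimate per land-cover class), T₁ and T₂ are temperature
stress scalars around the pixel's optimal temperature, and W ∈ [0.5, 1] is a
moisture stress scalar from an evapotranspiration ratio (or soil moisture).

**Drought indices.** SPEI at 1/3/12-month scales: the k-month accumulated
climatic water balance `D = P − PET` (Thornthwaite PET) is fitted per pixel
and calendar month with a three-parameter log-logistic distribution via
L-moments and mapped to a standard normal deviate. SSMI: the stratified
z-score `(SM − SM̄)/σ` of the k-month soil-moisture running mean. Both are
graded into mild/moderate/severe/extreme drought, counted into a drought
frequency index `DFI = 100·m/M`, and the aridity index is classed
humid / semi-humid / semi-arid / arid at the 1 / 1.5 / 4 boundaries.

**Statistics.** Per-pixel Theil-Sen slopes with tie-corrected Mann-Kendall
significance; per-pixel Pearson and partial correlations (inverse
correlation-matrix formulation) of annual NPP against precipitation,
temperature and radiation; season-aligned correlations with SPEI-3/12 and
SSMI.

**Impact and validation.** ΔNPP tables: percent NPP change in drought
months relative to a per-class, per-calendar-month non-drought baseline,
stratified by severity; early (Mar–May) vs peak (Jun–Aug) growing-season
comparison; and POD/FAR/CSI skill of a monthly regional drought flag
against a dated drought-event catalog.

A synthetic-data module generates the whole input stack with known embedded
structure (seasonal cycles, linear trends, gamma precipitation, a
leaky-bucket soil moisture coupled to PET, class-specific NDVI–precipitation
coupling, dated drought episodes), so every stage can be validated against
recoverable ground truth without any external download.

## Worked example

```
droughtnpp run-all --outdir out --seed 1
droughtnpp summarize out/manifest.json
```

which prints (abridged):

```
drought-NPP pipeline summary
==============================
mean annual NPP: 427.93 gC/m2/a
mean annual T: 10.93 degC; mean annual P: 558.63 mm
Sen slope precip_total_mm: 2.726/a (p=0.00582)
Sen slope temp_mean_degC: 0.02041/a (p=1.3e-09)
NPP~precip (pearson): mean r=0.932, positive 100.0%, significant 100.0%
skill: POD=0.7500 FAR=0.1176 CSI=0.6818 (H=30 M=10 F=4)
dNPP grassland/severe: -60.4% (n=2428)
```

Reading this: the default synthetic scenario is a 40×40 grid over
2001–2020 with an annual-mean temperature of 10.74 °C warming at
0.02 °C/a and ~580 mm of summer-concentrated annual precipitation rising at
2.65 mm/a — the recovered Sen slopes (0.0204 °C/a, 2.73 mm/a) match what
the generator embedded. Precipitation drives NDVI (and hence NPP) in the
scenario, so the NPP–precipitation correlation field is strongly positive.
The embedded drought-episode calendar is detected by the SPEI-3 regional
flag with POD 0.75 / FAR 0.12, and grassland loses the most NPP in severe
drought months relative to its non-drought baseline.

The same chain runs on real rasters by setting `synthetic: false` and
listing input paths in the YAML config (see `droughtnpp.pipeline.RunConfig`);
inputs must be pre-aligned on one grid — the package never resamples
silently.

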