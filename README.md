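# fieldet

Daily, field-scale crop water use (evaporation) from high-resolution NDVI
rasters and hourly flux-tower meteorology, using the Priestley–Taylor
PT-JPL latent-heat model, with energy-closure-corrected evaluation, water
depth accounting, and field variability analytics. A seeded synthetic
scene generator makes the whole pipeline testable without external data.

## What it does

- **`fieldet.synthetic_data`** — double-logistic NDVI phenology scenes
  with heterogeneity patches, diurnal meteorology with stochastic cloud
  attenuation, and tower flux records generated from a reference model
  run plus an imposed energy-balance closure gap and noise.
- **`fieldet.forcing_io`** — AmeriFlux-style CSV ingestion (−9999
  sentinel, RH percent→fraction), daytime masking (Rn > 0), linear
  gap-filling, negative-daytime-LE screening, residual closure correction
  (LE = Rn − G − H), GeoTIFF NDVI stacks, GeoJSON boundaries, and site
  management logs.
- **`fieldet.ptjpl_core`** — psychrometrics, NDVI-derived vegetation
  indices (SAVI, fAPAR, fIPAR, LAI), the five biophysical constraints
  (f_g, f_wet, f_T, f_M, f_SM), Beer–Lambert radiation partitioning,
  diurnal-cosine soil heat flux, and the soil/canopy/interception flux
  components (LE = LE_s + LE_c + LE_i).
- **`fieldet.water_accounting`** — W/m² → mm/h conversion
  (E = LE·3600/λ), daily aggregation, pixel-center zonal statistics,
  Savitzky–Golay smoothing, cumulative E-vs-precipitation accounting,
  cumulative E maps and underperformance masks.
- **`fieldet.evaluation`** — hourly model-vs-tower pairing and r², bias
  (plus range-normalized bias) and MAE statistics.

## CLI

```sh
# generate a synthetic scene (NDVI GeoTIFFs, tower CSV, boundary, truth)
fieldet simulate --outdir scene --seed 7

# run the full analysis (daily series, cumulative accounting, rasters)
fieldet run --met scene/tower.csv --ndvi-dir scene/ndvi \
    --boundary scene/boundary.geojson --timezone -6 --longitude -96.4766 \
    --outdir products

# evaluate modeled E against closure-corrected tower fluxes
fieldet evaluate --met scene/tower.csv --ndvi-dir scene/ndvi \
    --boundary scene/boundary.geojson --timezone -6 --longitude -96.4766 \
    --outdir evalout

# summarize a run directory (JSON summary + figure)
fieldet report --rundir products
```

All knobs (PT-JPL constants, smoothing window/order, season bounds,
synthetic-scene parameters) can be set in a YAML config passed with
`--config`; CLI flags override it.

## Conventions

- Hourly records are half-open intervals [t, t+1h) stamped at t, in
  local standard time; solar geometry uses the interval midpoint and
  ignores the equation of time.
- Daytime is defined as Rn > 0; nighttime E contributes 0 to daily
  totals.
- Zonal statistics use pixel-center containment; moments use the
  population (1/n) convention.
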