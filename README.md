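# gridshed

Convert daily gridded ambient-pollutant surfaces (per-cell concentration and
standard error) into census block-group concentration estimates, and roll
those up into population-weighted exposure series for tracts, counties,
states, and the nation — with NAAQS exceedance summaries, population-at-risk
tables, and station-based validation statistics.

## Method

1. **Downscale** — for each block group (BG) centroid, find the four nearest
   grid centroids by Vincenty geodesic distance on WGS84, weight them by
   inverse squared distance `w_i = (1/d_i²) / Σ (1/d_j²)`, and form per-day
   estimates `μ = Σ w_i P_i` with standard error `δ = sqrt(Σ w_i² σ_i²)`.
   Coincident centroids (d = 0) take the continuous limit: they absorb all
   the weight, split equally if there are several.
2. **Aggregate** — population-weighted mean per census unit:
   `PE = Σ (pop_i / Σ pop_j) μ_i`, `ψ = sqrt(Σ a_i² δ_i²)`. Units nest by
   FIPS GEOID prefix (state 2 / county 5 / tract 11 / BG 12 digits).
3. **Summarize** — tail-percentile day-rank summaries (the 98th percentile
   of a 365-day series is the 7th-highest day), strict exceedance-day counts
   against the daily standards (35 μg/m³ PM2.5, 75 ppb ozone), 5-class map
   breaks anchored at the standard (PM2.5: 15/25/35/45; ozone: 55/65/75/85),
   and population-at-risk tables over minimum-exceedance-day criteria.
4. **Validate** — pair BG estimates with ground-station observations on
   (BG, date) and report MAD, pooled Pearson R, and the absolute-deviation
   distribution, stratified by year, meteorological season, or urban/rural.

A synthetic-data module generates all pipeline inputs (smooth spatial field
with seasonal and AR(1) temporal structure, nested block-group geography
with populations, noisy stations) so every stage is testable offline.

## CLI

All I/O is headered, comma-separated UTF-8 text. GEOIDs are zero-padded
strings, dates ISO-8601, floats written at full double precision so reruns
are byte-identical.

```sh
# generate a synthetic dataset (grid.csv, bg.csv, stations.csv, truth.csv)
gridshed simulate --config sim.yaml --out-dir data/

# individual stages
gridshed downscale --grid data/grid.csv --bg data/bg.csv --out bg_est.csv
gridshed aggregate --bg-est bg_est.csv --bg data/bg.csv \
    --levels tract,county,state,national --out exposures.csv
gridshed summarize --exposures exposures.csv --bg-est bg_est.csv \
    --bg data/bg.csv --pollutant pm25 --min-days 7,14,28 --out summary_dir/
gridshed validate --bg-est bg_est.csv --stations data/stations.csv \
    --strata year,season --out report.csv

# or the full chain
gridshed run --grid data/grid.csv --bg data/bg.csv \
    --stations data/stations.csv --strata year,season --out-dir out/
```

Input schemas:

| table    | columns |
|----------|---------|
| grid     | `cell_id, lat, lon, date, value, se` |
| bg       | `geoid` (12 digits), `lat, lon, population` |
| stations | `station_id, bg_geoid, date, observed[, urban_rural]` |

Station-to-BG assignment is an input column; produce it externally with any
point-in-polygon tool against BG boundary polygons.

## Notes and conventions

- Ellipsoid: WGS84; Vincenty inverse iterated to 1e-12 rad (cap 200); nearly
  antipodal pairs raise `ConvergenceError` rather than looping.
- Neighbor ties break by ascending `cell_id`; the KD-tree fast path is
  exactly equivalent to brute-force search.
- "Exceeding" means strictly greater than the standard.
- The day rank is `k = max(1, round(p·D))`, half away from zero; the applied
  `k` is exposed in the summary output (`p98_k`, `p90_k`).
- ψ is reported as a standard error (square root of the weighted variance
  sum); independence is assumed across grid cells and across BGs, which can
  understate the true uncertainty.
- Zero-population BGs carry no exposure and are dropped from weighting;
  zero-population units are reported with missing percentages.
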