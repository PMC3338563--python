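# pollivalue

Valuation of the benefits humans derive from animal pollination of
crops: country-level time series, national vulnerability indicators,
fine-resolution gridded benefit maps, and a trend-surface regression
describing the spatial pattern — plus a seeded synthetic-data generator
so the entire pipeline can be exercised end-to-end with known ground
truth, without downloading any external statistics.

## Who this is for

Ecosystem-service and agro-economic researchers who work with
FAO-style country × crop × year panels (production quantities and
producer prices), macroeconomic correction factors (inflation,
purchasing power parity), and gridded crop-distribution products
(per-crop yield and cultivated-area-fraction rasters on a lat-lon
lattice).

## The model

The pollination benefit in year *t* is the pollination-attributable
share of crop production, valued at corrected producer prices:

```
V_t = Σ_i Σ_j  pp_ijt · pq_ijt · dr_i · inf_jt · ppp_jt
```

for crops *i* and countries *j*, where `pp` is the nominal producer
price ($/ton), `pq` the production quantity (tons), `dr` the crop's
pollination dependency ratio (with literature lower/median/upper
bounds), `inf` the inflation correction to a 2009 reference year and
`ppp` the purchasing-power-parity factor (1 for the reference country).
Its physical twin `Q_t = Σ pq·dr` (dependency-weighted tons) yields the
price signal `P_t = V_t / Q_t`, an implicit average corrected price of
pollination-dependent output; `V = P·Q` holds by construction.
Indexing all series to a 1993 base makes their trends comparable, and a
staple baseline (maize, rice, wheat, rye, yams, sorghum, taro — crops
that do not depend on pollinators) provides the contrast.

On the grid, production varies within countries: per cell, benefit =
yield (t/ha) × cultivated-area fraction × national corrected price ×
dr, in $ per hectare of *total* cell area, so per-crop maps share a
reference area and can be summed. Cells with a reported yield but no
cultivated-area information carry an explicit missing-data flag.
National vulnerability is the benefit as a share of GDP, or of
agricultural GDP (GDP × agricultural share). The spatial pattern is
described by penalized-spline additive models of log benefit on
temperature × precipitation, cropland fraction, and optionally a
bivariate coordinate smooth.

## Worked example

```python
import pollivalue as pv

cfg = pv.WorldConfig(n_countries=20, n_crops=8, n_staples=2, seed=42,
                     target_ag_dependency=0.10, beehive_trend_correlation=0.7)
world = pv.generate_world(cfg)
aligned = pv.align_panels(world.production, world.prices,
                          world.corrections, world.dependency)

V = pv.pollination_benefit(aligned, grouping="country")
Q = pv.weighted_quantity(aligned, grouping="country")
P = pv.price_signal(V, Q)
print(round(V.values.loc[2009].sum() / 1e9, 3))   # 2.337  (billion corrected $)

from pollivalue.vulnerability import vulnerability_table
tab = vulnerability_table(V.values, world.macro)
print(round(tab["ag_gdp_dependency"].mean(), 3))  # 0.1  (the construction target)

rasters = pv.generate_rasters(world)
```

The first number is the synthetic world's total pollination benefit in
2009 in billions of corrected US$; the second recovers, exactly, the
10 % agricultural-GDP dependency the world was built with — the
pipeline's consistency check from the macro side. Zonal aggregation of
the gridded maps reproduces the per-country `V` values to float
precision, closing the loop from the grid side.

A command-line interface mirrors the library:

```
pollivalue simulate --out world/           # synthetic CSVs + ASCII-grid rasters
pollivalue value --production world/production.csv --prices world/prices.csv \
    --corrections world/corrections.csv --deps world/dependency.csv \
    --group-by country --out series.csv
pollivalue vulnerability --benefit series.csv --macro world/macro.csv --out vuln.csv
pollivalue map --stack world/rasters --prices world/prices.csv \
    --corrections world/corrections.csv --deps world/dependency.csv --out maps/
pollivalue describe --benefit maps/benefit_total_median.asc \
    --temperature world/rasters/temperature.asc \
    --precipitation world/rasters/precipitation.asc \
    --cropland world/rasters/cropland.asc --out summary.json
```

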