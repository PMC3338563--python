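# Methods

## Valuation model

The package values pollination as the production-cost share of crop
output attributable to animal pollinators. For crop *i*, country *j*,
year *t*:

* benefit `V_t = Σ_ij pp·pq·dr_i·inf_jt·ppp_jt` in corrected US$,
* weighted quantity `Q_t = Σ_ij pq·dr_i` in tons,
* price signal `P_t = V_t / Q_t` in corrected $/ton.

`dr_i` is the crop's pollination dependency ratio — the fraction of
yield lost if animal pollination vanished — carried as a
lower/median/upper triple per crop to propagate the literature's
uncertainty. Staple crops (maize, rice, wheat, rye, yams, sorghum,
taro) are pollination-independent (`dr = 0`); the staple baseline runs
the same machinery with `dr` replaced by 1 restricted to those crops,
so benefit-like production values of dependent and independent crops
can be compared on equal footing.

Assumptions worth stating plainly: producer prices are taken as
marginal values for the entire attributable share (a production-cost
valuation, not a welfare measure — no demand response, no substitution
between production factors); dependency ratios are constant over
countries and years; and corrections are multiplicative
(`inf` to the 2009 reference year, `ppp` relative to a reference
country whose factor is 1).

### Choices where the design was open

* **Quantity corrections.** Applying inflation/PPP factors to tons is
  dimensionally odd, so `weighted_quantity` defaults to plain tons —
  this keeps `P = V/Q` in $/ton and the decomposition exact. A
  `monetary_corrections_on_quantity` flag provides the corrected
  variant for comparison.
* **Gaps.** Country-crop-years present in the production panel but
  lacking a price or correction factor are flagged, counted and
  excluded from sums — never silently imputed. An optional
  `country-mean` imputation fills a missing price with that
  country × crop's mean over observed years.
* **Aggregation.** Sums of products, never products of pre-averaged
  factors; pandas' compensated group sums keep results stable under
  row permutation to well below 1e-9 relative.
* **Global vulnerability** is a ratio of sums
  (`Σ benefit / Σ ag-GDP`), not a mean of national ratios, so large
  economies carry their economic weight. National ratios above 1 are
  flagged as data inconsistencies, not errors.
* **Outliers** in trend correlations and change regressions are
  explicit exclusion lists; there is no automatic detection.

## Gridded benefits

Per cell: `benefit [$/ha] = yield [t/harvested-ha] × area_fraction ×
national corrected price [$/t] × dr`. Relating the product to *total*
cell area gives all crops a common reference area, so per-crop maps
sum cell-wise. Mask semantics: yield present but area fraction absent
→ *missing data* (benefit exists but is uncomputable, flagged); yield
absent → plain nodata. The total map counts a cell valid if any crop
is valid there and does not propagate missing-data flags — a
conservative estimate, since unmapped crops could only add benefit.
Cell areas use the spherical band formula on the authalic sphere
(R = 6371.0088 km); zonal country totals are `Σ value × cell_area` by
a country-zone raster (lattice-exact, no polygon overlay). Crop area
fractions summing above 1 in a cell are reported but not renormalized,
mirroring how upstream crop-distribution products leave such
administrative inconsistencies in place. The map year is a single
configuration value (default 2000); rasters travel as plain-text ESRI
ASCII grids with cell-center registration, north-up, longitude in
[-180, 180).

## Trend-surface regression

Cells with positive benefit and complete predictors enter a table with
the natural-log benefit as response (zeros and missing cells are
excluded and counted). Models are penalized B-spline additive
regressions written for this package: cubic bases with equally spaced
knots, second-order difference penalties, tensor-product bases with
Kronecker-sum penalties for the bivariate temperature × precipitation
and coordinate smooths, and smoothing parameters chosen by minimizing
GCV (Nelder-Mead on log λ). Basis sizes default to 20 for univariate
smooths, 5 per margin (25 coefficients) for the climate interaction
and 7 per margin (49) for coordinates — small because the fits
describe broad spatial structure, and configurable. Reported
"explained variance" is the in-sample 1 − RSS/TSS (for a Gaussian
model this equals deviance explained); per-term p-values are
approximate F-tests from refitting without the term at fixed λ. The
second-difference penalty leaves linear functions unpenalized, so an
exactly linear signal is fit without bias. A subsampling option fits
on a seeded random subset when the cell table is large. These models
describe the current spatial pattern; they are not suitable for
climate-change projection.

## Synthetic worlds

The generator emulates the statistical structure of the real inputs —
not their magnitudes: log-normal country scales (σ = 1 by default,
giving the heavy right tail of national production), Dirichlet crop
shares with mild per-crop growth trends, producer prices with AR(1)
multiplicative log-noise (σ = 0.08/yr) and small drift, inflation
factors compounding at 1–6 %/yr toward the 2009 reference, constant
Penn-style PPP factors in 0.8–3.5 with one reference country at 1, and
a 1993–2009 window with the spatial snapshot at 2000. One seed drives
everything through per-component child seeds, so outputs are
bit-reproducible and extending the generator does not shift earlier
draws.

Three quantities are known by construction and anchor the tests:

1. with `target_ag_dependency` set, agricultural GDP is defined as
   benefit / target, so the vulnerability stage must recover the
   target exactly in every country-year;
2. with `beehive_trend_correlation = ρ`, beehive series are exactly
   linear with country slopes built (by Gram-Schmidt) to have sample
   correlation exactly ρ with the benefit trend slopes;
3. rasters allocate each country × crop national total over the
   country's cells with positive random weights encoded as
   yield × area-fraction layers, so zonal re-aggregation reproduces
   the panel to float precision.

Countries are contiguous rectangular blocks of cells — sufficient for
zonal logic and trivially verifiable, deliberately not realistic
shapes. Climate fields are simple (temperature falling with |latitude|,
smooth sinusoidal precipitation); cropland tracks the total cultivated
fraction with noise.

What passing tests therefore show: the pipeline's algebra, masks,
joins and aggregations are correct, and known signals are recovered at
the stated tolerances. What they do not show: robustness to the
reporting artifacts of real statistics (inconsistent country coverage,
revisions, price conversions), realistic spatial autocorrelation, or
the magnitudes of real benefit estimates.

## Problem sizes and numerical notes

Test and acceptance runs use worlds of 20–150 countries, 8–12 crops,
17 years and grids up to ~5,000 cells, and regression samples of
n = 2,000 — sizes chosen so the full suite completes in seconds while
every code path is exercised at realistic shape. Degenerate inputs are
flagged rather than dropped: zero weighted quantity yields an
undefined price signal, a zero base-year value blocks indexing, zero
GDP or agricultural share yields an undefined vulnerability record,
and a zero base year in relative changes marks the country excluded.
GCV optimization clamps log λ to ±25 and treats singular systems as
infinitely poor fits, which keeps the smoothing search inside the
numerically meaningful range.

## Known limitations

* Production-cost valuation only; the attributable-net-income variant
  is out of scope.
* No currency conversion (inputs are assumed pre-converted US$) and no
  trade/footprint adjustment of national vulnerability.
* No raster reprojection or resampling; all layers must share one
  lattice.
* The per-crop missing-data flag cannot be carried into the total map,
  so total benefits are conservative where crops are unmapped.
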