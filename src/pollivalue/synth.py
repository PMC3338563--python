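"""Seeded synthetic worlds: FAO-like panels and crop rasters with known truth.

The generator emulates the statistical structure of the real source
data — country x crop x year production panels with heterogeneous
country sizes and multiplicative price noise, inflation factors
drifting toward a 2009 reference year, Penn-style purchasing-power
factors with one reference country, World-Bank-style macro series, and
per-crop yield / area-fraction rasters whose zonal sums match the
national panel exactly — without attempting to match real-world
magnitudes.  Crucially, several quantities are known *by construction*:

* when ``target_ag_dependency`` is set, GDP and agricultural share are
  built so the agricultural-GDP dependency on pollination equals the
  target exactly in every year;
* when ``beehive_trend_correlation`` is set, beehive series are exactly
  linear with country slopes whose sample Pearson correlation with the
  benefit trend slopes equals rho exactly;
* the rasters allocate each country x crop production total across the
  country's cells so zonal re-aggregation reproduces the panel.

A single seed drives everything through per-component child seeds, so
outputs are reproducible and adding a component does not perturb the
draws of earlier ones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from pollivalue import data_model
from pollivalue.gridio import make_raster, write_ascii_grid
from pollivalue.spatial import CropRasterStack, cell_area

REFERENCE_YEAR = 2009

_STAPLE_NAMES = ("maize", "rice", "wheat", "rye", "yams", "sorghum", "taro")
_CROP_NAMES = (
    "apples", "almonds", "soybeans", "cotton", "pears", "cacao", "coffee",
    "rapeseed", "sunflower", "watermelons", "blueberries", "cucumbers",
    "avocados", "mustard", "vanilla", "kolanut", "coconut", "eggplants",
)


@dataclass
class WorldConfig:
    """Knobs of the synthetic world.

    Defaults mirror the study conditions of the analysis the pipeline
    implements: the 1993-2009 window with 2009 as inflation reference,
    a map year of 2000, moderate multiplicative price noise and a wide
    log-normal spread of country sizes.
    """

    n_countries: int = 50
    n_crops: int = 12
    n_staples: int = 3
    years: tuple[int, int] = (1993, 2009)
    seed: int = 0
    price_volatility: float = 0.08  # sd of year-to-year log price innovations
    inflation_drift: tuple[float, float] = (0.01, 0.06)  # per-year inflation rate range
    ppp_range: tuple[float, float] = (0.8, 3.5)
    size_dispersion: float = 1.0  # sd of log-normal country scale
    target_ag_dependency: float | None = None
    beehive_trend_correlation: float | None = None
    cells_per_country: int = 16
    resolution: float = 0.5  # degrees; 5 arcminutes = 1/12
    map_year: int = 2000

    def __post_init__(self):
        if self.n_staples > self.n_crops:
            raise ValueError("n_staples cannot exceed n_crops")
        if self.years[0] > self.years[1]:
            raise ValueError("invalid year range")
        if self.inflation_drift[0] > self.inflation_drift[1] or self.ppp_range[0] > self.ppp_range[1]:
            raise ValueError("invalid factor range")
        if self.ppp_range[0] <= 0:
            raise ValueError("ppp factors must be positive")
        if self.beehive_trend_correlation is not None and abs(self.beehive_trend_correlation) > 1:
            raise ValueError("|beehive_trend_correlation| must be <= 1")
        if self.target_ag_dependency is not None and not 0 < self.target_ag_dependency < 1:
            raise ValueError("target_ag_dependency must lie in (0, 1)")
        if not self.years[0] <= self.map_year <= self.years[1]:
            raise ValueError("map_year must lie inside the year window")

    @property
    def year_list(self) -> list[int]:
        return list(range(self.years[0], self.years[1] + 1))

    @property
    def country_ids(self) -> list[str]:
        return [f"C{j:03d}" for j in range(self.n_countries)]

    @property
    def crop_ids(self) -> list[str]:
        names = []
        for i in range(self.n_staples):
            names.append(_STAPLE_NAMES[i] if i < len(_STAPLE_NAMES) else f"staple_{i}")
        for i in range(self.n_crops - self.n_staples):
            names.append(_CROP_NAMES[i] if i < len(_CROP_NAMES) else f"crop_{i}")
        return names


@dataclass
class SyntheticWorld:
    """Generated panels plus construction-known ground truth."""

    config: WorldConfig
    dependency: pd.DataFrame
    production: pd.DataFrame
    prices: pd.DataFrame
    corrections: pd.DataFrame
    macro: pd.DataFrame
    truth: dict = field(default_factory=dict)


def _child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _benefit_by_country(world_tables, scenario: str = "dr_median") -> pd.DataFrame:
    """Direct product-sum benefit per country and year (median scenario)."""
    dependency, production, prices, corrections = world_tables
    t = production.merge(prices, on=["country_id", "crop_id", "year"])
    t = t.merge(corrections, on=["country_id", "year"])
    t = t.merge(dependency[["crop_id", scenario]], on="crop_id")
    t["v"] = t["price_nominal"] * t["quantity"] * t[scenario] * t["inflation_factor"] * t["ppp_factor"]
    return t.groupby(["year", "country_id"])["v"].sum().unstack()


def generate_world(config: WorldConfig) -> SyntheticWorld:
    """Generate the five panels of a synthetic world.

    Raises
    ------
    ValueError
        For infeasible targets, e.g. a dependency target when every
        crop is a pollination-independent staple.
    """
    rng_dep, rng_qty, rng_price, rng_corr, rng_macro, rng_bee, _ = _child_rngs(config.seed, 7)
    countries = config.country_ids
    crops = config.crop_ids
    years = config.year_list
    n_c, n_i, n_t = len(countries), len(crops), len(years)

    # dependency ratios: staples are pollination-independent (dr = 0)
    is_staple = np.array([i < config.n_staples for i in range(n_i)])
    med = np.where(is_staple, 0.0, 0.05 + 0.90 * rng_dep.beta(2.0, 2.0, n_i))
    low = np.where(is_staple, 0.0, med * rng_dep.uniform(0.3, 1.0, n_i))
    upp = np.where(is_staple, 0.0, med + (1.0 - med) * rng_dep.uniform(0.0, 0.7, n_i))
    dependency = pd.DataFrame(
        {"crop_id": crops, "dr_lower": low, "dr_median": med, "dr_upper": upp, "is_staple": is_staple}
    )

    # production quantities: log-normal country scale x crop share x mild trend x noise
    scale_c = np.exp(rng_qty.normal(0.0, config.size_dispersion, n_c)) * 1e5
    share_i = rng_qty.dirichlet(np.full(n_i, 2.0))
    growth_i = rng_qty.uniform(0.0, 0.04, n_i)
    t_idx = np.arange(n_t)
    noise = np.exp(rng_qty.normal(0.0, 0.15, (n_c, n_i, n_t)))
    pq = scale_c[:, None, None] * share_i[None, :, None] * (1 + growth_i)[None, :, None] ** t_idx * noise

    # producer prices: crop base level, country factor, AR(1) multiplicative noise + drift
    base_i = np.exp(rng_price.normal(np.log(300.0), 0.5, n_i))
    cfac = np.exp(rng_price.normal(0.0, 0.2, (n_c, n_i)))
    drift_i = rng_price.uniform(0.0, 0.02, n_i)
    eps = rng_price.normal(0.0, config.price_volatility, (n_c, n_i, n_t))
    ar = np.zeros_like(eps)
    for k in range(1, n_t):
        ar[:, :, k] = 0.7 * ar[:, :, k - 1] + eps[:, :, k]
    pp = base_i[None, :, None] * cfac[:, :, None] * np.exp(ar) * (1 + drift_i)[None, :, None] ** t_idx

    idx = pd.MultiIndex.from_product([countries, crops, years], names=["country_id", "crop_id", "year"])
    production = pd.DataFrame({"quantity": pq.ravel()}, index=idx).reset_index()
    prices = pd.DataFrame({"price_nominal": pp.ravel()}, index=idx).reset_index()

    # corrections: inflation compounds toward the 2009 reference year;
    # country 0 is the purchasing-power reference (ppp = 1 in all years)
    infl_rate = rng_corr.uniform(*config.inflation_drift, n_c)
    years_arr = np.array(years)
    inf = (1 + infl_rate)[:, None] ** np.maximum(REFERENCE_YEAR - years_arr, 0)[None, :]
    ppp_c = rng_corr.uniform(*config.ppp_range, n_c)
    ppp_c[0] = 1.0
    cidx = pd.MultiIndex.from_product([countries, years], names=["country_id", "year"])
    corrections = pd.DataFrame(
        {"inflation_factor": inf.ravel(), "ppp_factor": np.repeat(ppp_c, n_t)}, index=cidx
    ).reset_index()

    benefit_cy = _benefit_by_country((dependency, production, prices, corrections))

    # macro series: GDP and agricultural share; when a dependency target is
    # set, agricultural GDP is benefit / target so the indicator is exact
    ag_share_c = rng_macro.uniform(0.05, 0.35, n_c)
    if config.target_ag_dependency is not None:
        if not (benefit_cy.to_numpy() > 0).all():
            raise ValueError(
                "target_ag_dependency infeasible: some country-years have zero pollination benefit "
                "(e.g. all crops are staples)"
            )
        ag_gdp = benefit_cy / config.target_ag_dependency  # years x countries
        gdp_cy = (ag_gdp / pd.Series(ag_share_c, index=benefit_cy.columns)).T  # countries x years
    else:
        g_growth = rng_macro.uniform(0.0, 0.05, n_c)
        gdp_cy = pd.DataFrame(
            scale_c[:, None] * 5e3 * (1 + g_growth)[:, None] ** t_idx[None, :],
            index=pd.Index(countries, name="country_id"),
            columns=benefit_cy.index,
        )

    # beehives: exactly linear series; when rho is set the country slopes
    # have sample correlation exactly rho with the benefit trend slopes
    yv = years_arr.astype(float)
    yc = yv - yv.mean()
    bslope = (benefit_cy.to_numpy().T @ yc) / (yc @ yc)  # per-country OLS slope of benefit
    if config.beehive_trend_correlation is not None:
        rho = config.beehive_trend_correlation
        if n_c < 3 or np.std(bslope) == 0:
            raise ValueError("beehive_trend_correlation infeasible: benefit slopes have no variance")
        b_s = (bslope - bslope.mean()) / bslope.std()
        z = rng_bee.normal(0.0, 1.0, n_c)
        e = z - z.mean() - (z @ b_s) / (b_s @ b_s) * b_s  # residualize for exact sample rho
        if np.std(e) == 0:
            raise ValueError("degenerate beehive noise draw")
        hive_slope = rho * b_s + np.sqrt(1 - rho**2) * e / e.std()
    else:
        hive_slope = rng_bee.normal(0.0, 1.0, n_c)
    hive_slope = hive_slope * 50.0  # hives per year
    span = max(abs(yv - yv[0]).max(), 1.0)
    base_h = 1e4 * np.exp(rng_bee.normal(0.0, 0.5, n_c)) + np.abs(hive_slope) * span
    beehives = base_h[:, None] + hive_slope[:, None] * (yv - yv[0])[None, :]

    macro = pd.DataFrame(
        {
            "gdp": gdp_cy.to_numpy().ravel(),
            "ag_share": np.repeat(ag_share_c, n_t),
            "beehives": beehives.ravel(),
        },
        index=cidx,
    ).reset_index()

    truth = {
        "target_ag_dependency": config.target_ag_dependency,
        "beehive_trend_correlation": config.beehive_trend_correlation,
        "benefit_by_country_map_year": benefit_cy.loc[config.map_year].to_dict(),
        "global_benefit_by_year": benefit_cy.sum(axis=1).to_dict(),
    }
    world = SyntheticWorld(
        config=config,
        dependency=data_model.validate_panel(dependency, "dependency"),
        production=data_model.validate_panel(production, "production"),
        prices=data_model.validate_panel(prices, "price"),
        corrections=data_model.validate_panel(corrections, "corrections"),
        macro=data_model.validate_panel(macro, "macro"),
        truth=truth,
    )
    return world


@dataclass
class SyntheticRasters:
    """Crop raster stack plus climate and cropland layers."""

    stack: CropRasterStack
    temperature: xr.DataArray
    precipitation: xr.DataArray
    cropland: xr.DataArray


def generate_rasters(world: SyntheticWorld, config: WorldConfig | None = None) -> SyntheticRasters:
    """Build rasters consistent with the world's national totals.

    Countries occupy contiguous rectangular blocks of cells.  For every
    crop, the national map-year production is distributed over the
    country's cells with random positive weights and encoded as yield x
    area-fraction layers, so ``sum(yield * fraction * cell_area)`` over
    a country's cells reproduces the panel quantity to float precision.
    Temperature falls off with |latitude|, precipitation is a smooth
    field, and cropland tracks the total cultivated fraction — each with
    seeded noise.
    """
    config = config or world.config
    rng = _child_rngs(config.seed, 7)[6]
    countries = config.country_ids
    crops = config.crop_ids
    n_c, n_i = len(countries), len(crops)
    res = config.resolution

    bc = int(np.ceil(np.sqrt(config.cells_per_country)))
    br = int(np.ceil(config.cells_per_country / bc))
    ncx = int(np.ceil(np.sqrt(n_c)))
    ncy = int(np.ceil(n_c / ncx))
    nrows, ncols = ncy * br, ncx * bc
    if nrows * res > 180 or ncols * res > 360:
        raise ValueError("cells insufficient / grid too large to place all countries on the sphere")
    lat_max = min(nrows * res / 2, 90.0)
    lon_min = -ncols * res / 2

    zone = np.full((nrows, ncols), -1, dtype=int)
    for j in range(n_c):
        r0, c0 = (j // ncx) * br, (j % ncx) * bc
        zone[r0 : r0 + br, c0 : c0 + bc] = j

    template = make_raster(zone.astype(float), res, lat_max=lat_max, lon_min=lon_min)
    lats = template.coords["lat"].to_numpy()
    areas = cell_area(lats, res)[:, None] * np.ones((1, ncols))  # ha per cell

    # per-cell crop fractions: positive draws normalized to sum 0.9 per cell
    raw = rng.uniform(0.2, 1.0, (n_i, nrows, ncols))
    frac = 0.9 * raw / raw.sum(axis=0, keepdims=True)

    pq_map = world.production[world.production["year"] == config.map_year]
    pq_lut = pq_map.set_index(["country_id", "crop_id"])["quantity"]

    yields = np.full((n_i, nrows, ncols), np.nan)
    for j, cname in enumerate(countries):
        cells = zone == j
        k = int(cells.sum())
        for i, crop in enumerate(crops):
            w = rng.gamma(1.5, 1.0, k)
            w = w / w.sum()
            prod_cell = pq_lut.loc[(cname, crop)] * w  # tons per cell, sums to the national total
            yields[i][cells] = prod_cell / (frac[i][cells] * areas[cells])

    coords = {"crop": list(crops), "lat": template.coords["lat"], "lon": template.coords["lon"]}
    frac_da = xr.DataArray(np.where(zone >= 0, frac, np.nan), coords=coords, dims=("crop", "lat", "lon"))
    yield_da = xr.DataArray(yields, coords=coords, dims=("crop", "lat", "lon"))
    zone_da = xr.DataArray(zone, coords=template.coords, dims=("lat", "lon"))
    stack = CropRasterStack(
        yields=yield_da, area_fraction=frac_da, country_zone=zone_da, zone_names=tuple(countries)
    )

    lat2d = np.broadcast_to(lats[:, None], (nrows, ncols))
    lon2d = np.broadcast_to(template.coords["lon"].to_numpy()[None, :], (nrows, ncols))
    temperature = 28.0 - 0.45 * np.abs(lat2d) + rng.normal(0.0, 1.5, (nrows, ncols))
    precipitation = np.clip(
        900.0
        + 500.0 * np.sin(np.radians(lon2d) * 3.0)
        + 300.0 * np.cos(np.radians(lat2d) * 4.0)
        + rng.normal(0.0, 120.0, (nrows, ncols)),
        0.0,
        None,
    )
    total_frac = np.nansum(frac_da.to_numpy(), axis=0)
    cropland = np.clip(total_frac * rng.uniform(0.8, 1.1, (nrows, ncols)) + rng.normal(0.0, 0.03, (nrows, ncols)), 0.0, 1.0)

    mk = lambda a, name: make_raster(a, res, lat_max=lat_max, lon_min=lon_min, name=name)
    return SyntheticRasters(
        stack=stack,
        temperature=mk(temperature, "temperature"),
        precipitation=mk(precipitation, "precipitation"),
        cropland=mk(cropland, "cropland"),
    )


def write_world(world: SyntheticWorld, out_dir, rasters: SyntheticRasters | None = None) -> None:
    """Write the five CSVs (plus rasters and truth.json) to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    data_model.write_panel(world.production, out / "production.csv", "production")
    data_model.write_panel(world.prices, out / "prices.csv", "price")
    data_model.write_panel(world.corrections, out / "corrections.csv", "corrections")
    data_model.write_panel(world.macro, out / "macro.csv", "macro")
    data_model.write_panel(world.dependency, out / "dependency.csv", "dependency")
    with open(out / "truth.json", "w") as fh:
        json.dump({"config": asdict(world.config), "truth": world.truth}, fh, indent=2, default=str)
    if rasters is not None:
        rdir = out / "rasters"
        rdir.mkdir(exist_ok=True)
        for crop in rasters.stack.crops:
            write_ascii_grid(rasters.stack.yields.sel(crop=crop), rdir / f"yield_{crop}.asc")
            write_ascii_grid(rasters.stack.area_fraction.sel(crop=crop), rdir / f"area_{crop}.asc")
        write_ascii_grid(rasters.stack.country_zone.astype(float), rdir / "zones.asc")
        write_ascii_grid(rasters.temperature, rdir / "temperature.asc")
        write_ascii_grid(rasters.precipitation, rdir / "precipitation.asc")
        write_ascii_grid(rasters.cropland, rdir / "cropland.asc")
        with open(rdir / "zone_names.json", "w") as fh:
            json.dump(list(rasters.stack.zone_names), fh)
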