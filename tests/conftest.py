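import numpy as np
import pandas as pd
import pytest
import xarray as xr

from pollivalue import WorldConfig, align_panels, generate_rasters, generate_world
from pollivalue.spatial import CropRasterStack


@pytest.fixture(scope="session")
def small_world():
    """20-country world with construction-known dependency and trend targets."""
    cfg = WorldConfig(
        n_countries=20,
        n_crops=8,
        n_staples=2,
        seed=42,
        target_ag_dependency=0.10,
        beehive_trend_correlation=0.7,
        cells_per_country=16,
    )
    return generate_world(cfg)


@pytest.fixture(scope="session")
def small_aligned(small_world):
    w = small_world
    return align_panels(w.production, w.prices, w.corrections, w.dependency)


@pytest.fixture(scope="session")
def small_rasters(small_world):
    return generate_rasters(small_world)


def random_panel(seed, n_countries=5, n_crops=8, n_years=4):
    """A small random panel for brute-force oracle checks."""
    rng = np.random.default_rng(seed)
    countries = [f"C{j}" for j in range(n_countries)]
    crops = [f"crop{i}" for i in range(n_crops)]
    years = list(range(1993, 1993 + n_years))
    idx = pd.MultiIndex.from_product([countries, crops, years], names=["country_id", "crop_id", "year"])
    production = pd.DataFrame({"quantity": rng.uniform(1, 1e4, len(idx))}, index=idx).reset_index()
    prices = pd.DataFrame({"price_nominal": rng.uniform(10, 2000, len(idx))}, index=idx).reset_index()
    cidx = pd.MultiIndex.from_product([countries, years], names=["country_id", "year"])
    corrections = pd.DataFrame(
        {"inflation_factor": rng.uniform(1, 2, len(cidx)), "ppp_factor": rng.uniform(0.5, 3, len(cidx))},
        index=cidx,
    ).reset_index()
    corrections.loc[corrections["country_id"] == "C0", "ppp_factor"] = 1.0
    corrections.loc[corrections["year"] == years[-1], "inflation_factor"] = 1.0
    med = rng.uniform(0.05, 0.9, n_crops)
    dependency = pd.DataFrame(
        {
            "crop_id": crops,
            "dr_lower": med * rng.uniform(0.2, 1, n_crops),
            "dr_median": med,
            "dr_upper": med + (1 - med) * rng.uniform(0, 0.8, n_crops),
            "is_staple": [False] * n_crops,
        }
    )
    return production, prices, corrections, dependency


def brute_force_benefit(production, prices, corrections, dependency, dr_col="dr_median", ppp=True):
    """Naive triple-loop benefit per year (the independent oracle for the sums)."""
    dep = dependency.set_index("crop_id")[dr_col]
    pr = prices.set_index(["country_id", "crop_id", "year"])["price_nominal"]
    co = corrections.set_index(["country_id", "year"])
    out: dict[int, float] = {}
    for row in production.itertuples():
        key = (row.country_id, row.crop_id, row.year)
        if key not in pr.index or (row.country_id, row.year) not in co.index:
            continue
        c = co.loc[(row.country_id, row.year)]
        term = pr.loc[key] * row.quantity * dep.loc[row.crop_id] * c["inflation_factor"]
        if ppp:
            term *= c["ppp_factor"]
        out[row.year] = out.get(row.year, 0.0) + term
    return out


@pytest.fixture
def tiny_stack():
    """Handcrafted 3x3 single-country stack exercising every mask case.

    Crop a: cell (0,1) has yield but no area fraction (missing data);
    cell (0,2) has fraction but no yield (plain nodata).
    """
    lat = [1.0, 0.5, 0.0]
    lon = [0.0, 0.5, 1.0]
    coords = {"crop": ["a", "b"], "lat": lat, "lon": lon}
    y = np.full((2, 3, 3), 2.0)
    f = np.full((2, 3, 3), 0.25)
    y[0, 0, 2] = np.nan  # fraction present, yield nodata -> invalid
    f[0, 0, 1] = np.nan  # yield present, fraction nodata -> missing_data
    yields = xr.DataArray(y, coords=coords, dims=("crop", "lat", "lon"))
    fracs = xr.DataArray(f, coords=coords, dims=("crop", "lat", "lon"))
    zone = xr.DataArray(np.zeros((3, 3), dtype=int), coords={"lat": lat, "lon": lon}, dims=("lat", "lon"))
    return CropRasterStack(yields=yields, area_fraction=fracs, country_zone=zone, zone_names=("C0",))
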