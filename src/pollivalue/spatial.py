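"""Gridded pollination-benefit maps on a latitude-longitude lattice.

Per-crop benefit maps follow the same valuation logic as the national
sums, but production is allowed to vary within countries: each cell
carries a crop yield (tons per harvested hectare) and the fraction of
the cell cultivated with the crop.  Multiplying yield by area fraction
by the national corrected producer price by the crop's dependency ratio
gives the pollination benefit in $ per hectare of *total* cell area — a
common reference area, so per-crop maps can be summed.

Mask semantics follow the upstream crop-distribution products: a cell
with a reported yield but no cultivated-area information is *missing
data* (benefit uncomputable, flagged); a cell with no yield is plain
nodata.  The total map treats a cell as valid if any crop is valid
there and does not propagate per-crop missing-data flags — a
conservative choice, since unmapped crops can only add benefit.

Zonal aggregation (cell value x latitude-dependent spherical cell area,
summed per country zone) closes the loop with the national valuation.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from pollivalue.gridio import raster_resolution

EARTH_RADIUS_M = 6371008.8  # authalic mean radius
_M2_PER_HA = 1e4
OVERALLOCATION_TOL = 1e-9


@dataclass
class CropRasterStack:
    """Per-crop yield and area-fraction grids plus a country-zone grid.

    ``yields`` and ``area_fraction`` share dims (crop, lat, lon); the
    zone raster assigns each cell an index into ``zone_names`` (-1 for
    no country).  All layers share one lattice (shape and coordinates).
    """

    yields: xr.DataArray
    area_fraction: xr.DataArray
    country_zone: xr.DataArray
    zone_names: tuple[str, ...]
    overallocated_cells: int = field(init=False, default=0)

    def __post_init__(self):
        if self.yields.dims != ("crop", "lat", "lon") or self.area_fraction.dims != ("crop", "lat", "lon"):
            raise ValueError("yield and area_fraction layers must have dims (crop, lat, lon)")
        if self.yields.shape != self.area_fraction.shape:
            raise ValueError("yield and area_fraction layers must share shape")
        if self.country_zone.shape != self.yields.shape[1:]:
            raise ValueError("country_zone must share the (lat, lon) lattice")
        for da in (self.area_fraction, self.country_zone):
            if not np.array_equal(da.coords["lat"], self.yields.coords["lat"]) or not np.array_equal(
                da.coords["lon"], self.yields.coords["lon"]
            ):
                raise ValueError("all layers must share lat/lon coordinates")
        frac = self.area_fraction.to_numpy()
        finite = np.isfinite(frac)
        if ((frac[finite] < 0) | (frac[finite] > 1)).any():
            raise ValueError("area fractions must lie in [0, 1] where defined")
        total = np.nansum(frac, axis=0)
        over = total > 1 + OVERALLOCATION_TOL
        self.overallocated_cells = int(over.sum())
        if self.overallocated_cells:
            # reported, not renormalised: over-allocation reflects upstream
            # administrative inconsistencies, not an error in this layer
            warnings.warn(
                f"{self.overallocated_cells} cell(s) have crop area fractions summing > 1",
                stacklevel=2,
            )

    @property
    def crops(self) -> list[str]:
        return [str(c) for c in self.yields.coords["crop"].to_numpy()]

    @property
    def resolution(self) -> float:
        return raster_resolution(self.yields)


@dataclass
class BenefitRaster:
    """Per-cell pollination benefit in corrected $ per hectare of total cell area.

    ``values`` holds NaN on invalid cells; ``missing_data`` flags cells
    where a yield was reported but no cultivated area (benefit exists
    but is uncomputable).  The two masks are disjoint by construction.
    """

    values: xr.DataArray
    missing_data: xr.DataArray

    def __post_init__(self):
        if self.values.shape != self.missing_data.shape:
            raise ValueError("values and missing_data must share the lattice")
        v = self.values.to_numpy()
        valid = np.isfinite(v)
        if (v[valid] < 0).any():
            raise ValueError("benefit values must be non-negative where valid")
        if (valid & self.missing_data.to_numpy().astype(bool)).any():
            raise ValueError("valid and missing_data masks must be disjoint")

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.values.to_numpy())


def cell_area(lat_center, resolution: float):
    """Area in hectares of a lat-lon cell centred at ``lat_center`` degrees.

    Spherical band formula A = R^2 * d_lambda * (sin(phi2) - sin(phi1))
    on the authalic sphere; symmetric in +-lat and strictly decreasing
    towards the poles (band edges are clipped at +-90).
    """
    lat = np.asarray(lat_center, dtype=float)
    if (np.abs(lat) > 90).any():
        raise ValueError("latitude must lie in [-90, 90]")
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    phi1 = np.radians(np.clip(lat - resolution / 2, -90, 90))
    phi2 = np.radians(np.clip(lat + resolution / 2, -90, 90))
    dlam = np.radians(resolution)
    area = EARTH_RADIUS_M**2 * dlam * (np.sin(phi2) - np.sin(phi1)) / _M2_PER_HA
    return float(area) if area.ndim == 0 else area


def _zone_price_layer(stack: CropRasterStack, prices) -> np.ndarray:
    """Per-cell corrected price from the country-zone raster; NaN where no price."""
    zone = stack.country_zone.to_numpy().astype(int)
    lut = np.full(len(stack.zone_names), np.nan)
    for k, name in enumerate(stack.zone_names):
        if name in prices:
            lut[k] = prices[name]
    layer = np.full(zone.shape, np.nan)
    in_zone = zone >= 0
    layer[in_zone] = lut[zone[in_zone]]
    return layer


def crop_benefit_map(stack: CropRasterStack, crop_id: str, prices, dr: float) -> BenefitRaster:
    """Benefit map for one crop: yield x area_fraction x corrected price x dr.

    ``prices`` maps country_id -> corrected producer price ($/ton) for
    this crop.  Cells whose country zone has production but no price are
    flagged and excluded with a logged count.  Cells with yield but no
    area fraction form the missing-data mask.
    """
    if crop_id not in stack.crops:
        raise KeyError(f"crop {crop_id!r} not in stack (has {stack.crops})")
    if not 0 <= dr <= 1:
        raise ValueError("dependency ratio must lie in [0, 1]")
    y = stack.yields.sel(crop=crop_id).to_numpy()
    f = stack.area_fraction.sel(crop=crop_id).to_numpy()
    price = _zone_price_layer(stack, prices)

    has_yield = np.isfinite(y)
    missing = has_yield & ~np.isfinite(f)
    computable = has_yield & np.isfinite(f)
    no_price = computable & ~np.isfinite(price)
    if no_price.any():
        warnings.warn(
            f"crop {crop_id!r}: {int(no_price.sum())} cell(s) in zones without a price; excluded",
            stacklevel=2,
        )
    vals = np.full(y.shape, np.nan)
    ok = computable & np.isfinite(price)
    vals[ok] = y[ok] * f[ok] * price[ok] * dr
    template = stack.country_zone
    return BenefitRaster(
        values=xr.DataArray(vals, coords=template.coords, dims=template.dims, name=f"benefit_{crop_id}"),
        missing_data=xr.DataArray(missing, coords=template.coords, dims=template.dims),
    )


def total_benefit_map(crop_maps) -> BenefitRaster:
    """Cell-wise sum of per-crop benefit maps on a shared lattice.

    Invalid cells contribute 0 where at least one crop is valid; a cell
    is invalid only when invalid for every crop.  Per-crop missing-data
    flags are not propagated (the total is conservative: unmapped crops
    could only raise it); the returned mask is all-False.
    """
    crop_maps = list(crop_maps)
    if not crop_maps:
        raise ValueError("need at least one crop map")
    ref = crop_maps[0].values
    for m in crop_maps[1:]:
        if m.values.shape != ref.shape or not np.array_equal(m.values.coords["lat"], ref.coords["lat"]):
            raise ValueError("all crop maps must share the lattice")
    stackv = np.stack([m.values.to_numpy() for m in crop_maps])
    any_valid = np.isfinite(stackv).any(axis=0)
    total = np.where(any_valid, np.nansum(stackv, axis=0), np.nan)
    return BenefitRaster(
        values=xr.DataArray(total, coords=ref.coords, dims=ref.dims, name="benefit_total"),
        missing_data=xr.DataArray(np.zeros(ref.shape, dtype=bool), coords=ref.coords, dims=ref.dims),
    )


def aggregate_to_country(benefit: BenefitRaster, zones: xr.DataArray, zone_names) -> pd.Series:
    """National benefit totals: sum of value ($/ha) x cell area (ha) per zone.

    Valid benefit cells falling outside every zone are flagged with a
    warning.  Countries whose zone holds no valid cells get 0.
    """
    if zones.shape != benefit.values.shape:
        raise ValueError("zone raster must share the benefit lattice")
    res = raster_resolution(benefit.values)
    area = cell_area(benefit.values.coords["lat"].to_numpy(), res)  # per row
    vals = benefit.values.to_numpy()
    zone = zones.to_numpy().astype(int)
    valid = np.isfinite(vals)
    orphan = valid & (zone < 0)
    if orphan.any():
        warnings.warn(f"{int(orphan.sum())} valid benefit cell(s) outside every country zone", stacklevel=2)
    dollars = np.where(valid, vals, 0.0) * area[:, None]
    take = valid & (zone >= 0)
    totals = np.bincount(zone[take], weights=dollars[take], minlength=len(zone_names))
    return pd.Series(totals, index=pd.Index(list(zone_names), name="country_id"), name="benefit")


@dataclass
class ScenarioMaps:
    """Total benefit maps under the three dependency-bound scenarios."""

    maps: dict[str, BenefitRaster]
    correlations: dict[tuple[str, str], float]


def scenario_maps(stack: CropRasterStack, prices: pd.DataFrame, dependency: pd.DataFrame) -> ScenarioMaps:
    """Total maps for lower/median/upper dependency bounds, with pairwise r.

    ``prices`` is a long table (country_id, crop_id, price) of corrected
    producer prices for the map year.  Per-cell ordering
    lower <= median <= upper holds wherever all three are valid; the
    pairwise Pearson correlations over jointly valid cells quantify how
    little the spatial *pattern* depends on the dependency bound chosen.
    """
    dep = dependency.set_index("crop_id")
    out: dict[str, BenefitRaster] = {}
    for scen, col in (("lower", "dr_lower"), ("median", "dr_median"), ("upper", "dr_upper")):
        per_crop = []
        for crop in stack.crops:
            cp = prices[prices["crop_id"] == crop].set_index("country_id")["price"].to_dict()
            per_crop.append(crop_benefit_map(stack, crop, cp, float(dep.loc[crop, col])))
        out[scen] = total_benefit_map(per_crop)
    corr: dict[tuple[str, str], float] = {}
    for a, b in itertools.combinations(("lower", "median", "upper"), 2):
        va, vb = out[a].values.to_numpy().ravel(), out[b].values.to_numpy().ravel()
        joint = np.isfinite(va) & np.isfinite(vb)
        if joint.sum() >= 3 and np.std(va[joint]) > 0 and np.std(vb[joint]) > 0:
            corr[(a, b)] = float(np.corrcoef(va[joint], vb[joint])[0, 1])
        else:
            corr[(a, b)] = np.nan
    return ScenarioMaps(maps=out, correlations=corr)
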