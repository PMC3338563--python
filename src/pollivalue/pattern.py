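"""Describing the spatial pattern of pollination benefits.

How far do climate (mean annual temperature, annual precipitation) and
the distribution of cropland explain where pollination benefits arise?
This module builds the cell-level regression table (log-transformed
positive benefits joined with the predictor rasters), computes raster
correlations, and fits trend-surface additive models — optionally with
a bivariate smooth of the coordinates that absorbs spatial structure
not captured by the predictors.  The fits describe the present pattern;
they are not meant for projecting climate-change impacts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from pollivalue.gam import TrendSurfaceGAM
from pollivalue.spatial import BenefitRaster

FORMULAS = {
    "climate": (("te", "temperature", "precipitation", 5),),
    "cropland": (("s", "cropland_fraction", 20),),
    "climate+cropland": (
        ("te", "temperature", "precipitation", 5),
        ("s", "cropland_fraction", 20),
    ),
}
_COORD_TERM = ("te", "lon", "lat", 7)


@dataclass
class RegressionTable:
    """Cell-level table for the trend-surface fit, with exclusion accounting.

    ``table`` has one row per usable cell with columns log_benefit,
    temperature, precipitation, cropland_fraction, lon, lat.  The counts
    satisfy ``len(table) + n_excluded_zero + n_excluded_missing ==
    n_valid_benefit``.
    """

    table: pd.DataFrame
    n_valid_benefit: int
    n_excluded_zero: int
    n_excluded_missing: int


@dataclass
class CorrelationResult:
    r: float
    n: int
    undefined: bool = False


@dataclass
class TrendSurfaceFit:
    """Summary of a fitted trend-surface model."""

    formula: str
    include_coordinate_smooth: bool
    n: int
    explained_variance: float
    edf: float
    gcv: float
    term_table: pd.DataFrame
    model: TrendSurfaceGAM

    def to_dict(self) -> dict:
        return {
            "formula": self.formula,
            "coords_smooth": self.include_coordinate_smooth,
            "n": self.n,
            "explained_variance": self.explained_variance,
            "edf": self.edf,
            "gcv": self.gcv,
            "terms": self.term_table.to_dict(orient="records"),
        }


def _check_lattice(ref: xr.DataArray, other: xr.DataArray, name: str):
    if other.shape != ref.shape or not np.array_equal(other.coords["lat"], ref.coords["lat"]) or not np.array_equal(
        other.coords["lon"], ref.coords["lon"]
    ):
        raise ValueError(f"{name} raster does not share the benefit lattice")


def build_regression_table(
    benefit: BenefitRaster,
    temperature: xr.DataArray,
    precipitation: xr.DataArray,
    cropland: xr.DataArray,
) -> RegressionTable:
    """Join the benefit map with predictor rasters into a cell-level table.

    Zero-benefit cells and cells missing any predictor are excluded
    before the natural-log transform of the response; both exclusion
    counts are reported.
    """
    v = benefit.values
    for name, da in (("temperature", temperature), ("precipitation", precipitation), ("cropland", cropland)):
        _check_lattice(v, da, name)
    vals = v.to_numpy().ravel()
    valid = np.isfinite(vals)
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise ValueError("benefit raster has no valid cells")
    zero = valid & (vals == 0)
    preds = {
        "temperature": temperature.to_numpy().ravel(),
        "precipitation": precipitation.to_numpy().ravel(),
        "cropland_fraction": cropland.to_numpy().ravel(),
    }
    pred_ok = np.ones(vals.shape, dtype=bool)
    for arr in preds.values():
        pred_ok &= np.isfinite(arr)
    keep = valid & ~zero & pred_ok
    n_missing = int((valid & ~zero & ~pred_ok).sum())
    if not keep.any():
        raise ValueError("no usable cells after filtering zeros and missing predictors")
    lon2d, lat2d = np.meshgrid(v.coords["lon"].to_numpy(), v.coords["lat"].to_numpy())
    table = pd.DataFrame(
        {
            "log_benefit": np.log(vals[keep]),
            "temperature": preds["temperature"][keep],
            "precipitation": preds["precipitation"][keep],
            "cropland_fraction": preds["cropland_fraction"][keep],
            "lon": lon2d.ravel()[keep],
            "lat": lat2d.ravel()[keep],
        }
    )
    return RegressionTable(
        table=table,
        n_valid_benefit=n_valid,
        n_excluded_zero=int(zero.sum()),
        n_excluded_missing=n_missing,
    )


def raster_correlation(a: xr.DataArray, b: xr.DataArray) -> CorrelationResult:
    """Pearson correlation between two rasters over jointly valid cells."""
    if a.shape != b.shape:
        raise ValueError("rasters must share the lattice")
    va, vb = a.to_numpy().ravel(), b.to_numpy().ravel()
    joint = np.isfinite(va) & np.isfinite(vb)
    n = int(joint.sum())
    if n < 3:
        raise ValueError(f"raster_correlation requires >= 3 jointly valid cells, got {n}")
    xa, xb = va[joint], vb[joint]
    if np.std(xa) == 0 or np.std(xb) == 0:
        return CorrelationResult(np.nan, n, undefined=True)
    return CorrelationResult(float(np.corrcoef(xa, xb)[0, 1]), n)


def fit_trend_surface(
    table,
    formula: str = "climate+cropland",
    include_coordinate_smooth: bool = False,
    subsample: int | None = None,
    seed: int | None = None,
) -> TrendSurfaceFit:
    """Fit a trend-surface additive model of log benefit on the predictors.

    Parameters
    ----------
    table
        A :class:`RegressionTable` or its DataFrame.
    formula
        ``"climate"`` (tensor smooth of temperature x precipitation),
        ``"cropland"`` (univariate smooth), or ``"climate+cropland"``.
    include_coordinate_smooth
        Add a bivariate smooth of (lon, lat) absorbing residual spatial
        structure.
    subsample
        Fit on a seeded random subset of at most this many rows (the
        global 5-arcminute table is far larger than the fit needs).
    """
    df = table.table if isinstance(table, RegressionTable) else pd.DataFrame(table)
    if formula not in FORMULAS:
        raise ValueError(f"unknown formula {formula!r}; expected one of {sorted(FORMULAS)}")
    if subsample is not None and len(df) > subsample:
        df = df.sample(n=subsample, random_state=seed)
    terms = FORMULAS[formula] + ((_COORD_TERM,) if include_coordinate_smooth else ())
    model = TrendSurfaceGAM(terms=terms).fit(df, df["log_benefit"].to_numpy())
    return TrendSurfaceFit(
        formula=formula,
        include_coordinate_smooth=include_coordinate_smooth,
        n=model.n_obs_,
        explained_variance=model.explained_variance_,
        edf=model.edf_,
        gcv=model.gcv_,
        term_table=model.term_table_,
        model=model,
    )
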