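"""Plain-text raster I/O (ESRI ASCII grid).

Rasters travel in and out of the package as ESRI ASCII grids (.asc):
a six-line header (ncols, nrows, xllcorner, yllcorner, cellsize,
NODATA_value) followed by rows of whitespace-separated values, northmost
row first.  In memory a raster is an :class:`xarray.DataArray` with
``lat``/``lon`` cell-center coordinates (degrees, geographic CRS,
north-up, longitudes in [-180, 180)) and NaN for nodata.
"""

from __future__ import annotations

import numpy as np
import xarray as xr

DEFAULT_NODATA = -9999.0


def grid_coords(n_lat: int, n_lon: int, resolution: float, lat_max: float, lon_min: float):
    """Cell-center latitude/longitude vectors for a north-up grid."""
    lats = lat_max - resolution / 2 - resolution * np.arange(n_lat)
    lons = lon_min + resolution / 2 + resolution * np.arange(n_lon)
    return lats, lons


def make_raster(data: np.ndarray, resolution: float, lat_max: float = 90.0, lon_min: float = -180.0,
                name: str | None = None) -> xr.DataArray:
    """Wrap a 2-D array (north-up) into a lat/lon DataArray."""
    data = np.asarray(data, dtype=float)
    lats, lons = grid_coords(data.shape[0], data.shape[1], resolution, lat_max, lon_min)
    return xr.DataArray(data, coords={"lat": lats, "lon": lons}, dims=("lat", "lon"), name=name,
                        attrs={"resolution": resolution, "crs": "EPSG:4326"})


def raster_resolution(da: xr.DataArray) -> float:
    lat = da.coords["lat"].to_numpy()
    if len(lat) > 1:
        return float(abs(lat[1] - lat[0]))
    return float(da.attrs.get("resolution"))


def write_ascii_grid(da: xr.DataArray, path, nodata: float = DEFAULT_NODATA) -> None:
    """Write a lat/lon DataArray as an ESRI ASCII grid (NaN -> nodata)."""
    res = raster_resolution(da)
    lat = da.coords["lat"].to_numpy()
    lon = da.coords["lon"].to_numpy()
    data = da.to_numpy().astype(float)
    if len(lat) > 1 and lat[1] > lat[0]:  # ensure north-up on disk
        data = data[::-1]
        lat = lat[::-1]
    out = np.where(np.isfinite(data), data, nodata)
    header = (
        f"ncols {data.shape[1]}\n"
        f"nrows {data.shape[0]}\n"
        f"xllcorner {lon[0] - res / 2:.10g}\n"
        f"yllcorner {lat[-1] - res / 2:.10g}\n"
        f"cellsize {res:.10g}\n"
        f"NODATA_value {nodata:.10g}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt="%.10g")


def read_ascii_grid(path) -> xr.DataArray:
    """Read an ESRI ASCII grid into a lat/lon DataArray (nodata -> NaN)."""
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        data = np.loadtxt(fh)
    data = np.atleast_2d(data)
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    if data.shape != (nrows, ncols):
        raise ValueError(f"grid payload shape {data.shape} does not match header ({nrows}, {ncols})")
    nodata = header.get("nodata_value", DEFAULT_NODATA)
    data = np.where(data == nodata, np.nan, data)
    res = header["cellsize"]
    lat_max = header["yllcorner"] + nrows * res
    lon_min = header["xllcorner"]
    return make_raster(data, res, lat_max=lat_max, lon_min=lon_min)
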