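"""Gridded containers and NetCDF I/O.

All grids are plain :class:`xarray.Dataset` / :class:`xarray.DataArray`
objects with dimensions ``(time, lat, lon)`` (or ``(lat, lon)`` for land
cover).  Coordinates are integer indices, not geographic coordinates: the
pipeline is resolution-agnostic and keeps its bookkeeping in index space.
Missing values are NaN; a pixel is "valid" when its full series is finite.

Conventions
-----------
* ``time`` is an integer axis.  For monthly grids it counts months since
  January of ``attrs["start_year"]``; for 15-day composite grids it counts
  composites (two per calendar month).
* ``attrs["cadence"]`` is ``"monthly"`` or ``"15day"``.
* Units live in per-variable ``attrs["units"]``: ``degC``, ``mm/month``,
  and dimensionless NDVI in [-1, 1].

Files are written as NetCDF3 (classic) through xarray's scipy engine,
which round-trips these integer/float arrays exactly.
"""

from __future__ import annotations

import numpy as np
import xarray as xr

__all__ = [
    "climate_dataset",
    "ndvi_dataset",
    "landcover_array",
    "check_shared_axes",
    "to_netcdf",
    "open_dataset",
]


def climate_dataset(
    temperature: np.ndarray,
    precipitation: np.ndarray,
    start_year: int,
) -> xr.Dataset:
    """Bundle monthly temperature (degC) and precipitation (mm/month) grids."""
    if temperature.shape != precipitation.shape:
        raise ValueError(
            f"temperature {temperature.shape} and precipitation "
            f"{precipitation.shape} must share one (time, lat, lon) shape"
        )
    n_time, n_lat, n_lon = temperature.shape
    ds = xr.Dataset(
        {
            "temperature": (("time", "lat", "lon"), temperature, {"units": "degC"}),
            "precipitation": (
                ("time", "lat", "lon"),
                precipitation,
                {"units": "mm/month"},
            ),
        },
        coords={
            "time": np.arange(n_time),
            "lat": np.arange(n_lat),
            "lon": np.arange(n_lon),
        },
        attrs={"cadence": "monthly", "start_year": int(start_year)},
    )
    return ds


def ndvi_dataset(values: np.ndarray, start_year: int, cadence: str) -> xr.Dataset:
    """Bundle an NDVI grid; ``cadence`` is ``"15day"`` or ``"monthly"``."""
    if cadence not in ("15day", "monthly"):
        raise ValueError(f"unknown cadence {cadence!r}")
    n_time, n_lat, n_lon = values.shape
    return xr.Dataset(
        {"ndvi": (("time", "lat", "lon"), values, {"units": "1"})},
        coords={
            "time": np.arange(n_time),
            "lat": np.arange(n_lat),
            "lon": np.arange(n_lon),
        },
        attrs={"cadence": cadence, "start_year": int(start_year)},
    )


def landcover_array(codes: np.ndarray, scheme_size: int) -> xr.DataArray:
    """Categorical land-cover codes on a (lat, lon) grid, codes 1..scheme_size."""
    codes = np.asarray(codes)
    if codes.ndim != 2:
        raise ValueError("land cover must be 2-D (lat, lon)")
    bad = (codes < 1) | (codes > scheme_size)
    if bad.any():
        raise ValueError(f"codes outside 1..{scheme_size}")
    n_lat, n_lon = codes.shape
    return xr.DataArray(
        codes.astype(np.int32),
        dims=("lat", "lon"),
        coords={"lat": np.arange(n_lat), "lon": np.arange(n_lon)},
        name="landcover",
        attrs={"scheme_size": int(scheme_size)},
    )


def check_shared_axes(*grids: xr.Dataset | xr.DataArray, spatial_only: bool = False) -> None:
    """Raise if the grids do not share identical (time,) lat, lon axes.

    Guards against silent broadcasting across mismatched grids.
    """
    ref = grids[0]
    for g in grids[1:]:
        for dim in ("lat", "lon") if spatial_only else ("time", "lat", "lon"):
            if dim not in g.sizes or dim not in ref.sizes:
                continue
            if g.sizes[dim] != ref.sizes[dim]:
                raise ValueError(
                    f"grid axis mismatch on {dim!r}: {ref.sizes[dim]} vs {g.sizes[dim]}"
                )


def to_netcdf(ds: xr.Dataset | xr.DataArray, path) -> None:
    """Write NetCDF3 (classic) via the scipy engine."""
    if isinstance(ds, xr.DataArray):
        ds = ds.to_dataset()
    ds.to_netcdf(path, engine="scipy")


def open_dataset(path) -> xr.Dataset:
    """Read a dataset written by :func:`to_netcdf` fully into memory."""
    with xr.open_dataset(path, engine="scipy") as ds:
        return ds.load()
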