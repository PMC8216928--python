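"""From raw composite grids to aligned, windowed per-pixel datasets.

The chain is: maximum-value compositing of the 15-day NDVI composites to
monthly, block-mean regridding of the fine NDVI grid onto the coarse
climate grid, dominant-class aggregation of the land cover, strict
validity filtering, and slicing each surviving pixel's series into
6-month windows for the sequence models.

The train/validation split defaults to 264 training months followed by
144 validation months (22 + 12 years).  Inputs are z-scored per channel
using training-split statistics only; NDVI targets are left in native
units so RMSE is reported on the NDVI scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from .grids import check_shared_axes, ndvi_dataset

__all__ = [
    "PixelDataset",
    "WindowedSamples",
    "mvc_composite",
    "regrid_mean",
    "dominant_landcover",
    "filter_valid_pixels",
    "pixel_index_frame",
    "window_series",
]

WINDOW = 6  # months per model window


@dataclass
class PixelDataset:
    """One valid pixel's aligned monthly series and its split/normalization.

    ``norm_mean`` / ``norm_sd`` are per-channel (temperature,
    precipitation) statistics of the *training* months only; validation
    data never leaks into them.
    """

    pixel_id: int
    lat_idx: int
    lon_idx: int
    temperature: np.ndarray = field(repr=False)
    precipitation: np.ndarray = field(repr=False)
    ndvi: np.ndarray = field(repr=False)
    train_months: int
    landcover_code: int | None = None
    norm_mean: np.ndarray = field(init=False, repr=False)
    norm_sd: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        n = len(self.ndvi)
        if not (len(self.temperature) == len(self.precipitation) == n):
            raise ValueError("series lengths differ within a pixel")
        if not (0 < self.train_months < n):
            raise ValueError("train_months must split the series in two")
        tr = slice(0, self.train_months)
        x = np.stack([self.temperature[tr], self.precipitation[tr]], axis=1)
        self.norm_mean = x.mean(axis=0)
        sd = x.std(axis=0)
        self.norm_sd = np.where(sd > 0, sd, 1.0)

    @property
    def n_months(self) -> int:
        return len(self.ndvi)

    @property
    def val_months(self) -> int:
        return self.n_months - self.train_months

    def inputs_normalized(self) -> np.ndarray:
        """(n_months, 2) z-scored inputs using train-only statistics."""
        x = np.stack([self.temperature, self.precipitation], axis=1)
        return (x - self.norm_mean) / self.norm_sd


@dataclass
class WindowedSamples:
    """Fixed-length windows over one split of a pixel's series.

    ``x`` is (n_windows, window, 2) normalized climate, ``y`` is
    (n_windows, window) NDVI, ``starts`` are window start months in
    series coordinates.
    """

    x: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)
    starts: np.ndarray = field(repr=False)
    stride: int
    split: str

    @property
    def n_windows(self) -> int:
        return self.x.shape[0]

    @property
    def window(self) -> int:
        return self.x.shape[1]

    def tiles_exactly(self) -> bool:
        """True when the windows tile their span contiguously without overlap."""
        return self.stride == self.window and bool(
            np.all(np.diff(self.starts) == self.window)
        )


def mvc_composite(fine_ndvi: xr.Dataset) -> xr.Dataset:
    """Monthly NDVI by maximum-value compositing of 15-day composites.

    The monthly value is the maximum over the month's two composites,
    ignoring missing ones; a month with no finite composite stays
    missing.  Maximum compositing suppresses contamination that only
    depresses NDVI (clouds, aerosols).
    """
    if fine_ndvi.attrs.get("cadence") != "15day":
        raise ValueError("mvc_composite expects a 15-day composite grid")
    n_time = fine_ndvi.sizes["time"]
    if n_time % 2:
        raise ValueError(f"odd composite count {n_time}; expected two per month")
    vals = fine_ndvi["ndvi"].values
    shaped = vals.reshape(n_time // 2, 2, *vals.shape[1:])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN months stay NaN
        monthly = np.nanmax(shaped, axis=1)
    return ndvi_dataset(monthly, fine_ndvi.attrs["start_year"], "monthly")


def _block_view(a: np.ndarray, factor: int) -> np.ndarray:
    """Reshape trailing (lat, lon) axes into (lat/f, lon/f, f*f) blocks."""
    *lead, n_lat, n_lon = a.shape
    if n_lat % factor or n_lon % factor:
        raise ValueError(
            f"grid {n_lat}x{n_lon} not divisible by regrid factor {factor}"
        )
    b = a.reshape(*lead, n_lat // factor, factor, n_lon // factor, factor)
    b = np.moveaxis(b, -3, -2)
    return b.reshape(*lead, n_lat // factor, n_lon // factor, factor * factor)


def regrid_mean(fine: xr.Dataset, factor: int) -> xr.Dataset:
    """Coarsen NDVI by unweighted block means, ignoring missing cells.

    A coarse cell whose block is entirely missing stays missing.  No
    cos-latitude weighting: coordinates are grid indices, not degrees.
    """
    if factor == 1:
        return fine.copy(deep=True)
    blocks = _block_view(fine["ndvi"].values, factor)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN blocks stay NaN
        coarse = np.nanmean(blocks, axis=-1)
    return ndvi_dataset(coarse, fine.attrs["start_year"], fine.attrs["cadence"])


def dominant_landcover(fine: xr.DataArray, factor: int) -> xr.DataArray:
    """Dominant (modal) land-cover class per coarse block; ties -> lowest code."""
    if factor == 1:
        return fine.copy(deep=True)
    blocks = _block_view(fine.values.astype(np.int64), factor)
    nb_lat, nb_lon, _ = blocks.shape
    out = np.empty((nb_lat, nb_lon), dtype=np.int32)
    for i in range(nb_lat):
        for j in range(nb_lon):
            counts = np.bincount(blocks[i, j])
            out[i, j] = counts.argmax()  # argmax returns the lowest code on ties
    return xr.DataArray(
        out,
        dims=("lat", "lon"),
        coords={"lat": np.arange(nb_lat), "lon": np.arange(nb_lon)},
        name="landcover",
        attrs=dict(fine.attrs),
    )


def filter_valid_pixels(
    ndvi: xr.Dataset,
    climate: xr.Dataset,
    landcover: xr.DataArray | None = None,
    train_months: int = 264,
) -> list[PixelDataset]:
    """Keep only pixels whose full NDVI and climate series are finite.

    Strict rule: one missing month anywhere excludes the pixel — the
    per-pixel sequence models require gap-free series.  Each survivor
    becomes a :class:`PixelDataset` with the configured split.
    """
    if ndvi.attrs.get("cadence") != "monthly":
        raise ValueError("filter_valid_pixels expects monthly NDVI")
    check_shared_axes(ndvi, climate)
    if landcover is not None:
        check_shared_axes(ndvi, landcover, spatial_only=True)
    v = ndvi["ndvi"].values
    t = climate["temperature"].values
    p = climate["precipitation"].values
    ok = np.isfinite(v).all(axis=0) & np.isfinite(t).all(axis=0) & np.isfinite(p).all(axis=0)
    n_lat, n_lon = ok.shape
    datasets: list[PixelDataset] = []
    for i in range(n_lat):
        for j in range(n_lon):
            if not ok[i, j]:
                continue
            datasets.append(
                PixelDataset(
                    pixel_id=i * n_lon + j,
                    lat_idx=i,
                    lon_idx=j,
                    temperature=t[:, i, j].copy(),
                    precipitation=p[:, i, j].copy(),
                    ndvi=v[:, i, j].copy(),
                    train_months=train_months,
                    landcover_code=(
                        int(landcover.values[i, j]) if landcover is not None else None
                    ),
                )
            )
    if not datasets:
        raise ValueError("no valid pixels survived filtering")
    return datasets


def pixel_index_frame(datasets: list[PixelDataset]) -> pd.DataFrame:
    """Tidy index of pixel datasets (pixel_id, position, land cover)."""
    return pd.DataFrame(
        {
            "pixel_id": [d.pixel_id for d in datasets],
            "lat_idx": [d.lat_idx for d in datasets],
            "lon_idx": [d.lon_idx for d in datasets],
            "landcover_code": [d.landcover_code for d in datasets],
        }
    )


def _windows(x: np.ndarray, y: np.ndarray, offset: int, stride: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n = len(y)
    if n < WINDOW:
        raise ValueError(f"split of {n} months is shorter than the {WINDOW}-month window")
    starts = np.arange(0, n - WINDOW + 1, stride)
    xw = np.stack([x[s : s + WINDOW] for s in starts])
    yw = np.stack([y[s : s + WINDOW] for s in starts])
    return xw, yw, starts + offset

def window_series(
    ds: PixelDataset, train_stride: int = 1, val_stride: int = WINDOW
) -> tuple[WindowedSamples, WindowedSamples]:
    """Slice a pixel's series into 6-month training and validation windows.

    Training windows overlap (stride 1) to maximize samples; validation
    windows tile the split end to end (stride 6) so each validation month
    is predicted exactly once and the predictions concatenate back into
    the full monthly series.  No window crosses the split boundary.
    """
    x = ds.inputs_normalized()
    m = ds.train_months
    xt, yt, st = _windows(x[:m], ds.ndvi[:m], 0, train_stride)
    xv, yv, sv = _windows(x[m:], ds.ndvi[m:], m, val_stride)
    train = WindowedSamples(xt, yt, st, train_stride, "train")
    val = WindowedSamples(xv, yv, sv, val_stride, "val")
    return train, val
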