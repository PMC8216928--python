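"""Synthetic gridded climate / NDVI / land-cover generator with known truth.

The generator emulates the structure of the real inputs a gridded
vegetation-climate analysis consumes — 15-day NDVI composites on a fine
grid, monthly temperature and precipitation on a coarse grid, and a fine
categorical land-cover layer — while keeping the per-pixel climate
sensitivity *known*, so that every downstream stage (compositing,
regridding, per-pixel sequence models, permutation importance, error
attribution) can be tested against ground truth.

Generative model
----------------
Climate lives on the coarse (model) grid.  Per coarse pixel and month ``t``:

    T_t = T_lat + A_T * cos(2*pi*(m_t - 6)/12) + trend*(year_t - start) + eps_T
    P_t = max(0, P_lat * (1 + A_P * cos(2*pi*(m_t - 6)/12)) + eps_P)

with ``m_t`` the calendar month index (0..11), a latitude-dependent mean,
iid Gaussian monthly noise, and a linear warming trend that is constant
within each calendar year (which makes first/last-pentad temperature
differences exactly analytic).

The latent monthly NDVI signal per coarse pixel is

    s_t = base + season_amp * cos(2*pi*(m_t - 6)/12)
               + w_T * z(T, lag)_t + w_P * z(P, lag)_t + r_t
    r_t = ar_coef * r_{t-1} + N(0, noise_sd)
    ndvi_t = tanh(s_t)

where ``z(X, lag)`` is the *deseasonalized standardized lagged anomaly*:
subtract the pixel's month-of-year climatology, average the current and
previous ``lag - 1`` months, and divide by the standard deviation of that
lagged-mean series over the record (zero series stays zero).  Defining the
coupling on anomalies rather than raw values is deliberate: temperature
and precipitation share a seasonal cycle, and a coupling through raw
values would make the two inputs collinear — no importance measure could
then distinguish them.  The tanh squash keeps NDVI smoothly inside
(-1, 1) and is near-linear on the working range.

Each calendar month emits two 15-day composites per *fine* pixel: the
coarse latent value plus a static per-fine-pixel heterogeneity offset,
minus the absolute value of a Gaussian contamination draw (atmospheric
contamination only ever depresses NDVI, which is what maximum-value
compositing exploits), squashed by the same tanh.

Randomness is split into independent streams (climate / NDVI / land cover
/ invalidation) derived from one master seed, so regenerating one layer
never reshuffles the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

import numpy as np
import pandas as pd
import xarray as xr

from .grids import climate_dataset, landcover_array, ndvi_dataset

__all__ = [
    "GridSpec",
    "ResponseParams",
    "SyntheticTruth",
    "generate_climate",
    "generate_ndvi",
    "generate_landcover",
    "inject_invalid",
    "lagged_anomaly_z",
]

ArrayLike = Union[float, np.ndarray]

# stream tags for the per-operation RNGs derived from the master seed
_STREAM_CLIMATE = 1
_STREAM_NDVI = 2
_STREAM_LANDCOVER = 3
_STREAM_INVALID = 4


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream]))


@dataclass(frozen=True)
class GridSpec:
    """Grid geometry and period.

    ``fine_factor`` fine cells per coarse cell per axis (default 6,
    emulating 0.083 degree NDVI on a 0.5 degree climate grid); the period
    default emulates 34 years starting 1982.
    """

    n_lat: int
    n_lon: int
    fine_factor: int = 6
    n_years: int = 34
    start_year: int = 1982

    def __post_init__(self) -> None:
        if self.n_lat < 1 or self.n_lon < 1:
            raise ValueError("grid dimensions must be >= 1")
        if self.fine_factor < 1:
            raise ValueError("fine_factor must be >= 1")
        if self.n_years < 1:
            raise ValueError("n_years must be >= 1")

    @property
    def n_months(self) -> int:
        return 12 * self.n_years

    @property
    def n_composites(self) -> int:
        return 24 * self.n_years

    @property
    def fine_shape(self) -> tuple[int, int]:
        return (self.n_lat * self.fine_factor, self.n_lon * self.fine_factor)


@dataclass(frozen=True)
class ResponseParams:
    """Climate forcing and NDVI response parameters.

    ``w_T`` / ``w_P`` are unitless sensitivities (NDVI per standard
    deviation of the lagged climate anomaly), scalar or per-coarse-pixel
    ``(n_lat, n_lon)`` arrays.  ``noise_sd`` may likewise vary per pixel.
    Climate-side knobs: seasonal amplitudes, monthly noise sd, and a
    uniform linear warming trend (degC / year, stepped at year boundaries).
    """

    w_T: ArrayLike = 0.08
    w_P: ArrayLike = 0.08
    lag: int = 3
    base: float = 0.35
    season_amp: float = 0.25
    ar_coef: float = 0.3
    noise_sd: ArrayLike = 0.02
    trend_per_year: float = 0.03
    temp_season_amp: float = 10.0
    temp_noise_sd: float = 1.0
    precip_season_amp: float = 0.4
    precip_noise_sd: float = 20.0
    precip_mean: float = 80.0
    composite_noise_sd: float = 0.01
    fine_hetero_sd: float = 0.02

    def __post_init__(self) -> None:
        if self.lag < 1:
            raise ValueError("lag must be >= 1")
        if not (0 <= self.ar_coef < 1):
            raise ValueError("ar_coef must be in [0, 1)")


@dataclass
class SyntheticTruth:
    """Per-coarse-pixel ground truth for sensitivity recovery.

    ``table`` has one row per coarse pixel: pixel_id, lat_idx, lon_idx,
    w_T, w_P and the true class — ``temperature`` iff w_T > 0 and
    w_P == 0, ``precipitation`` iff w_P > 0 and w_T == 0, else ``both``.
    """

    table: pd.DataFrame = field(repr=False)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @property
    def classes(self) -> pd.Series:
        return self.table.set_index("pixel_id")["sens_class"]


def _true_class(w_t: float, w_p: float) -> str:
    if w_t > 0 and w_p == 0:
        return "temperature"
    if w_p > 0 and w_t == 0:
        return "precipitation"
    return "both"


def _month_index(n_months: int) -> np.ndarray:
    return np.arange(n_months) % 12


def _seasonal(n_months: int) -> np.ndarray:
    """Annual harmonic peaking in July (month index 6)."""
    return np.cos(2 * np.pi * (_month_index(n_months) - 6) / 12.0)


def _broadcast(value: ArrayLike, spec: GridSpec, name: str) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        return np.full((spec.n_lat, spec.n_lon), float(arr))
    if arr.shape != (spec.n_lat, spec.n_lon):
        raise ValueError(
            f"{name} must be scalar or shape {(spec.n_lat, spec.n_lon)}, got {arr.shape}"
        )
    return arr


def generate_climate(spec: GridSpec, params: ResponseParams, seed: int) -> xr.Dataset:
    """Monthly temperature and precipitation on the coarse grid.

    Temperature combines a latitudinal gradient (28 degC at the first row
    to -2 degC at the last), the seasonal harmonic, the year-stepped
    warming trend, and iid monthly noise.  Precipitation is a
    latitude-scaled mean with a relative seasonal cycle and additive
    noise, clipped at zero.
    """
    rng = _rng(seed, _STREAM_CLIMATE)
    n_months = spec.n_months
    lat_frac = (
        np.arange(spec.n_lat) / (spec.n_lat - 1)
        if spec.n_lat > 1
        else np.full(1, 0.5)
    )
    t_lat = 28.0 - 30.0 * lat_frac  # degC
    p_lat = params.precip_mean * (1.5 - lat_frac)  # mm/month

    season = _seasonal(n_months)
    year_idx = np.arange(n_months) // 12
    trend = params.trend_per_year * year_idx

    shape = (n_months, spec.n_lat, spec.n_lon)
    temp = (
        t_lat[None, :, None]
        + params.temp_season_amp * season[:, None, None]
        + trend[:, None, None]
        + params.temp_noise_sd * rng.standard_normal(shape)
    )
    precip = (
        p_lat[None, :, None] * (1.0 + params.precip_season_amp * season[:, None, None])
        + params.precip_noise_sd * rng.standard_normal(shape)
    )
    np.clip(precip, 0.0, None, out=precip)
    return climate_dataset(temp, precip, spec.start_year)


def lagged_anomaly_z(series: np.ndarray, lag: int) -> np.ndarray:
    """Deseasonalized standardized lagged anomaly of a monthly series.

    Steps: subtract the month-of-year climatology; replace each month by
    the mean of itself and the previous ``lag - 1`` months (truncated at
    the series start); divide by the standard deviation of that
    lagged-mean series over the record.  A constant series maps to zeros.

    ``series`` may be (time,) or (time, lat, lon); time is axis 0.
    """
    x = np.asarray(series, dtype=float)
    n = x.shape[0]
    months = _month_index(n)
    anom = np.empty_like(x)
    for m in range(12):
        sel = months == m
        anom[sel] = x[sel] - x[sel].mean(axis=0)
    # lagged running mean with truncation at the start
    csum = np.cumsum(anom, axis=0)
    lag = min(lag, n)
    out = np.empty_like(anom)
    for t in range(n):
        lo = max(0, t - lag + 1)
        out[t] = (csum[t] - (csum[lo - 1] if lo > 0 else 0.0)) / (t - lo + 1)
    sd = out.std(axis=0)
    # anomaly variance at float rounding level means "no anomalies":
    # standardizing it would amplify pure round-off into O(1) structure
    tol = 1e-8 * np.maximum(np.abs(x).max(axis=0), 1.0) + 1e-300
    live = sd > tol
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(live, out / np.where(live, sd, 1.0), 0.0)
    return z


def generate_ndvi(
    climate: xr.Dataset,
    spec: GridSpec,
    params: ResponseParams,
    seed: int,
) -> tuple[xr.Dataset, SyntheticTruth]:
    """Fine-grid 15-day NDVI composites driven by the coarse climate.

    Returns the fine composite grid (two composites per month) and the
    per-coarse-pixel truth table.  All values lie in (-1, 1) by the tanh
    squash.
    """
    if climate.sizes["time"] != spec.n_months:
        raise ValueError(
            f"climate has {climate.sizes['time']} months, spec implies {spec.n_months}"
        )
    if (climate.sizes["lat"], climate.sizes["lon"]) != (spec.n_lat, spec.n_lon):
        raise ValueError("climate grid does not match spec coarse dimensions")

    rng = _rng(seed, _STREAM_NDVI)
    n_months = spec.n_months
    w_t = _broadcast(params.w_T, spec, "w_T")
    w_p = _broadcast(params.w_P, spec, "w_P")
    noise_sd = _broadcast(params.noise_sd, spec, "noise_sd")

    z_t = lagged_anomaly_z(climate["temperature"].values, params.lag)
    z_p = lagged_anomaly_z(climate["precipitation"].values, params.lag)

    season = params.season_amp * _seasonal(n_months)[:, None, None]
    latent = params.base + season + w_t[None] * z_t + w_p[None] * z_p

    # AR(1) interannual noise on the latent scale
    innov = noise_sd[None] * rng.standard_normal((n_months, spec.n_lat, spec.n_lon))
    r = np.zeros_like(innov)
    r[0] = innov[0]
    for t in range(1, n_months):
        r[t] = params.ar_coef * r[t - 1] + innov[t]
    latent = latent + r

    # expand to the fine grid with static spatial heterogeneity
    f = spec.fine_factor
    fine_lat, fine_lon = spec.fine_shape
    latent_fine = np.repeat(np.repeat(latent, f, axis=1), f, axis=2)
    hetero = params.fine_hetero_sd * rng.standard_normal((fine_lat, fine_lon))
    latent_fine = latent_fine + hetero[None]

    # two 15-day composites per month; contamination only lowers NDVI
    contamination = np.abs(
        params.composite_noise_sd
        * rng.standard_normal((n_months, 2, fine_lat, fine_lon))
    )
    composites = np.tanh(latent_fine[:, None] - contamination)
    composites = composites.reshape(2 * n_months, fine_lat, fine_lon)

    rows = []
    for i in range(spec.n_lat):
        for j in range(spec.n_lon):
            rows.append(
                {
                    "pixel_id": i * spec.n_lon + j,
                    "lat_idx": i,
                    "lon_idx": j,
                    "w_T": w_t[i, j],
                    "w_P": w_p[i, j],
                    "sens_class": _true_class(w_t[i, j], w_p[i, j]),
                }
            )
    truth = SyntheticTruth(pd.DataFrame(rows))
    return ndvi_dataset(composites, spec.start_year, "15day"), truth


def generate_landcover(
    spec: GridSpec, n_classes: int, seed: int, block_size: int = 4
) -> xr.DataArray:
    """Spatially clumped categorical land cover on the fine grid.

    Classes 1..n_classes are assigned uniformly per ``block_size`` square
    block of fine cells.  The default block does not align with the
    coarse cells, so dominant-class aggregation is nontrivial.
    """
    if not (2 <= n_classes <= 17):
        raise ValueError("n_classes must be in 2..17")
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    rng = _rng(seed, _STREAM_LANDCOVER)
    fine_lat, fine_lon = spec.fine_shape
    nb_lat = -(-fine_lat // block_size)
    nb_lon = -(-fine_lon // block_size)
    blocks = rng.integers(1, n_classes + 1, size=(nb_lat, nb_lon))
    codes = np.repeat(np.repeat(blocks, block_size, axis=0), block_size, axis=1)
    return landcover_array(codes[:fine_lat, :fine_lon], scheme_size=17)


def inject_invalid(ndvi: xr.Dataset, fraction: float, seed: int) -> xr.Dataset:
    """Mark floor(fraction * n_pixels) pixels invalid (NaN whole series).

    Emulates the invalid-value pixels that real composites carry and the
    strict validity filter later deletes.
    """
    if not (0 <= fraction < 1):
        raise ValueError("fraction must be in [0, 1)")
    out = ndvi.copy(deep=True)
    n_lat, n_lon = out.sizes["lat"], out.sizes["lon"]
    n_bad = int(np.floor(fraction * n_lat * n_lon))
    if n_bad == 0:
        return out
    rng = _rng(seed, _STREAM_INVALID)
    flat = rng.choice(n_lat * n_lon, size=n_bad, replace=False)
    vals = out["ndvi"].values
    vals[:, flat // n_lon, flat % n_lon] = np.nan
    return out
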