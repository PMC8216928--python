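"""Climate/vegetation factors behind model error, and their regressions on CV.

Six per-pixel factors are computed over the full analysis period:

* MAT — mean annual temperature (degC), mean of the annual mean series;
* MAP — mean annual precipitation (mm/year), mean of the annual totals;
* dTMP — temperature change (degC): mean monthly temperature of the last
  five calendar years minus that of the first five;
* IAT / IAP / IAV — interannual variability: the coefficient of
  variation (sample sd / mean) of the annual series (annual mean
  temperature, annual total precipitation, annual mean NDVI).

Model error (validation CV) is then regressed on each factor across
pixels with ordinary least squares, one factor at a time, and stratified
by dominant land-cover class.

A note on IAT: a CV over a degC series is ill-defined when the annual
mean crosses or sits at zero; such pixels are computed on the Kelvin
scale instead, with a logged note.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr
from scipy import stats

from .grids import check_shared_axes

__all__ = [
    "ErrorFactors",
    "RegressionSummary",
    "FACTOR_NAMES",
    "compute_factors",
    "regress_cv_on_factor",
    "landcover_strata",
]

logger = logging.getLogger(__name__)

FACTOR_NAMES = ("mat", "map", "dtmp", "iat", "iap", "iav")
PENTAD = 5  # years in the first/last averaging windows of dTMP


@dataclass(frozen=True)
class ErrorFactors:
    """The six factors for one pixel."""

    pixel_id: int
    mat: float
    map: float
    dtmp: float
    iat: float
    iap: float
    iav: float


def _annual(series: np.ndarray, how: str) -> np.ndarray:
    """Aggregate a monthly (time, ...) array into annual means or totals."""
    n = series.shape[0]
    if n % 12:
        raise ValueError("monthly series length must be a multiple of 12")
    yearly = series.reshape(n // 12, 12, *series.shape[1:])
    return yearly.mean(axis=1) if how == "mean" else yearly.sum(axis=1)


def _cv_of(series: np.ndarray, ddof: int = 1) -> np.ndarray:
    """sd/mean along axis 0; zero-variance series -> 0, zero-mean -> nan."""
    mean = series.mean(axis=0)
    sd = series.std(axis=0, ddof=ddof)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(mean != 0, sd / np.where(mean != 0, mean, 1.0), np.nan)
    return np.where(sd == 0, 0.0, out)


def compute_factors(
    climate: xr.Dataset,
    ndvi: xr.Dataset,
    temp_aggregation: str = "mean",
    precip_aggregation: str = "sum",
    ndvi_aggregation: str = "mean",
    ddof: int = 1,
) -> pd.DataFrame:
    """Per-pixel factor table (pixel_id, mat, map, dtmp, iat, iap, iav).

    Requires at least 10 years so the first/last five-year dTMP windows
    do not overlap.  Pixels with any missing data get NaN factors.
    """
    if ndvi.attrs.get("cadence") != "monthly":
        raise ValueError("compute_factors expects monthly NDVI")
    check_shared_axes(climate, ndvi)
    t = climate["temperature"].values
    p = climate["precipitation"].values
    v = ndvi["ndvi"].values
    n_years = t.shape[0] // 12
    if n_years < 2 * PENTAD:
        raise ValueError(
            f"period of {n_years} years is too short: the {PENTAD}-year "
            "temperature-change windows would overlap"
        )

    t_ann = _annual(t, temp_aggregation)
    p_ann = _annual(p, precip_aggregation)
    v_ann = _annual(v, ndvi_aggregation)

    mat = t_ann.mean(axis=0)
    map_ = p_ann.mean(axis=0)
    dtmp = t[-12 * PENTAD :].mean(axis=0) - t[: 12 * PENTAD].mean(axis=0)

    iat = _cv_of(t_ann, ddof)
    # annual-mean temperatures at or below 0 degC make the CV ill-defined;
    # fall back to the Kelvin scale for those pixels
    bad = ~(t_ann.mean(axis=0) > 0)
    if bad.any():
        logger.warning(
            "%d pixel(s) with non-positive mean annual temperature: IAT on Kelvin scale",
            int(bad.sum()),
        )
        iat_k = _cv_of(t_ann + 273.15, ddof)
        iat = np.where(bad, iat_k, iat)
    iap = _cv_of(p_ann, ddof)
    iav = _cv_of(v_ann, ddof)

    n_lat, n_lon = mat.shape
    ids = np.arange(n_lat * n_lon)
    return pd.DataFrame(
        {
            "pixel_id": ids,
            "mat": mat.reshape(-1),
            "map": map_.reshape(-1),
            "dtmp": dtmp.reshape(-1),
            "iat": iat.reshape(-1),
            "iap": iap.reshape(-1),
            "iav": iav.reshape(-1),
        }
    )


@dataclass(frozen=True)
class RegressionSummary:
    """OLS of model CV on one factor across pixels."""

    factor: str
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def regress_cv_on_factor(
    vals: pd.DataFrame, factors: pd.DataFrame, factor: str
) -> RegressionSummary:
    """Ordinary least squares of validation CV on one factor across pixels."""
    if factor not in FACTOR_NAMES:
        raise ValueError(f"unknown factor {factor!r}; expected one of {FACTOR_NAMES}")
    merged = vals[["pixel_id", "cv"]].merge(
        factors[["pixel_id", factor]], on="pixel_id"
    ).dropna()
    if len(merged) < 3:
        raise ValueError("need at least 3 pixels with both CV and the factor")
    x = merged[factor].values.astype(float)
    if np.ptp(x) == 0:
        raise ValueError(f"factor {factor!r} has zero variance across pixels")
    res = stats.linregress(x, merged["cv"].values.astype(float))
    return RegressionSummary(
        factor=factor,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=len(merged),
    )


def landcover_strata(vals: pd.DataFrame, landcover: xr.DataArray) -> pd.DataFrame:
    """Per-land-cover-class mean/median/count of model CV, sorted by mean CV."""
    codes_flat = landcover.values.reshape(-1)
    df = vals[["pixel_id", "cv"]].copy()
    if df.empty:
        raise ValueError("no validation reports to stratify")
    if (df["pixel_id"] >= codes_flat.size).any():
        raise ValueError("pixel_id outside the land-cover grid")
    df["landcover_code"] = codes_flat[df["pixel_id"].values]
    out = (
        df.groupby("landcover_code")["cv"]
        .agg(mean_cv="mean", median_cv="median", n_pixels="count")
        .reset_index()
        .sort_values("mean_cv")
        .reset_index(drop=True)
    )
    return out


def factors_table(
    vals: pd.DataFrame,
    factors: pd.DataFrame,
    landcover: xr.DataArray | None = None,
    sensitivity: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One tidy per-pixel analysis table: cv, six factors, land cover, class."""
    out = vals[["pixel_id", "cv"]].merge(factors, on="pixel_id", how="left")
    if landcover is not None:
        codes_flat = landcover.values.reshape(-1)
        out["landcover_code"] = codes_flat[out["pixel_id"].values]
    if sensitivity is not None:
        out = out.merge(
            sensitivity[["pixel_id", "pit", "pip", "pid", "sens_class"]],
            on="pixel_id",
            how="left",
        )
    return out
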