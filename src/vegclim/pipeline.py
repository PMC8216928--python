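"""End-to-end run of a synthetic study: generate, preprocess, fit, analyze.

The bundle returned by :func:`run_scenario` carries every intermediate a
test or report needs; :func:`write_outputs` serializes the tables to CSV
and the grids to NetCDF so a rerun with the same master seed can be
checked for bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from . import error_attribution as ea
from .evaluate import (
    GridSummary,
    ValidationReport,
    grid_summary,
    validate_grid,
    validation_frame,
)
from .grids import to_netcdf
from .pixel_model import FitReport, PixelModel, fit_grid, reports_frame
from .preprocess import (
    PixelDataset,
    dominant_landcover,
    filter_valid_pixels,
    mvc_composite,
    pixel_index_frame,
    regrid_mean,
)
from .scenarios import Scenario
from .sensitivity import biome_sensitivity, sensitivity_grid
from .synthetic import (
    SyntheticTruth,
    generate_climate,
    generate_landcover,
    generate_ndvi,
    inject_invalid,
)

__all__ = ["PipelineResult", "run_scenario", "write_outputs"]


@dataclass
class PipelineResult:
    """Everything one scenario run produced."""

    scenario: Scenario
    seed: int
    climate: xr.Dataset = field(repr=False)
    ndvi_monthly: xr.Dataset = field(repr=False)
    landcover: xr.DataArray = field(repr=False)
    truth: SyntheticTruth = field(repr=False)
    datasets: list[PixelDataset] = field(repr=False)
    models: dict[int, tuple[PixelModel, FitReport]] = field(repr=False)
    fit_reports: pd.DataFrame = field(repr=False)
    validations: list[ValidationReport] = field(repr=False)
    validation_table: pd.DataFrame = field(repr=False)
    summary: GridSummary
    sensitivity: pd.DataFrame = field(repr=False)
    biome: pd.DataFrame = field(repr=False)
    factors: pd.DataFrame = field(repr=False)
    regressions: pd.DataFrame = field(repr=False)
    strata: pd.DataFrame = field(repr=False)


def run_scenario(scn: Scenario, seed: int) -> PipelineResult:
    """Run the full analysis on one synthetic scenario under one master seed."""
    spec, params = scn.spec, scn.params
    climate = generate_climate(spec, params, seed)
    fine_ndvi, truth = generate_ndvi(climate, spec, params, seed)
    if scn.invalid_fraction > 0:
        fine_ndvi = inject_invalid(fine_ndvi, scn.invalid_fraction, seed)
    lc_fine = generate_landcover(spec, scn.n_landcover_classes, seed)

    monthly_fine = mvc_composite(fine_ndvi)
    ndvi_coarse = regrid_mean(monthly_fine, spec.fine_factor)
    lc_coarse = dominant_landcover(lc_fine, spec.fine_factor)

    datasets = filter_valid_pixels(
        ndvi_coarse, climate, lc_coarse, train_months=scn.train_months
    )
    cfg = replace(scn.model, seed=seed)
    models = fit_grid(datasets, cfg)
    fits = reports_frame(models)
    vals = validate_grid(models, datasets)
    summary = grid_summary([r for _, r in models.values()], vals)

    sens = sensitivity_grid(models, datasets, n_repeats=scn.pi_repeats, seed=seed)
    biome = biome_sensitivity(sens, lc_coarse)

    factors = ea.compute_factors(climate, ndvi_coarse)
    vt = validation_frame(vals)
    reg_rows = []
    for name in ea.FACTOR_NAMES:
        try:
            r = ea.regress_cv_on_factor(vt, factors, name)
        except ValueError:
            continue  # degenerate factor on this scenario (e.g. zero variance)
        reg_rows.append(r.__dict__)
    regressions = pd.DataFrame(reg_rows)
    strata = ea.landcover_strata(vt, lc_coarse)

    return PipelineResult(
        scenario=scn,
        seed=seed,
        climate=climate,
        ndvi_monthly=ndvi_coarse,
        landcover=lc_coarse,
        truth=truth,
        datasets=datasets,
        models=models,
        fit_reports=fits,
        validations=vals,
        validation_table=vt,
        summary=summary,
        sensitivity=sens,
        biome=biome,
        factors=factors,
        regressions=regressions,
        strata=strata,
    )


def write_outputs(result: PipelineResult, out_dir) -> list[Path]:
    """Serialize tables to CSV and grids to NetCDF; returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []

    def _csv(df: pd.DataFrame, name: str) -> None:
        p = out / name
        df.to_csv(p, index=False, float_format="%.12g")
        paths.append(p)

    _csv(result.fit_reports, "fit_reports.csv")
    _csv(result.validation_table, "validation.csv")
    _csv(result.sensitivity, "sensitivity.csv")
    _csv(result.biome, "biome_sensitivity.csv")
    _csv(result.factors, "error_factors.csv")
    if len(result.regressions):
        _csv(result.regressions, "regressions.csv")
    _csv(result.strata, "landcover_strata.csv")
    _csv(result.truth.table, "truth.csv")
    _csv(result.summary.to_frame(), "summary.csv")
    _csv(pixel_index_frame(result.datasets), "pixel_index.csv")

    for name, grid in (
        ("climate.nc", result.climate),
        ("ndvi_monthly.nc", result.ndvi_monthly),
        ("landcover.nc", result.landcover),
        ("validation_series.nc", _validation_series(result)),
        ("sensitivity_class.nc", _class_grid(result)),
    ):
        p = out / name
        to_netcdf(grid, p)
        paths.append(p)
    return paths


_CLASS_CODES = {"temperature": 1, "precipitation": 2, "both": 3}


def _validation_series(result: PipelineResult) -> xr.Dataset:
    """Predicted and measured validation months per pixel, (pixel, time)."""
    pids = [v.pixel_id for v in result.validations]
    pred = np.stack([v.predicted_series for v in result.validations])
    meas = np.stack([v.measured_series for v in result.validations])
    n_val = pred.shape[1]
    t0 = result.scenario.train_months
    return xr.Dataset(
        {
            "predicted": (("pixel", "time"), pred),
            "measured": (("pixel", "time"), meas),
        },
        coords={"pixel": pids, "time": np.arange(t0, t0 + n_val)},
        attrs={"start_year": result.climate.attrs["start_year"]},
    )


def _class_grid(result: PipelineResult) -> xr.Dataset:
    """Integer-coded sensitivity classes on the coarse grid (0 = unfitted)."""
    n_lat = result.landcover.sizes["lat"]
    n_lon = result.landcover.sizes["lon"]
    codes = np.zeros((n_lat, n_lon), dtype=np.int32)
    for _, row in result.sensitivity.iterrows():
        pid = int(row["pixel_id"])
        codes[pid // n_lon, pid % n_lon] = _CLASS_CODES[row["sens_class"]]
    return xr.Dataset(
        {"sens_class": (("lat", "lon"), codes)},
        coords={"lat": np.arange(n_lat), "lon": np.arange(n_lon)},
        attrs={"codes": "1=temperature 2=precipitation 3=both 0=missing"},
    )
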