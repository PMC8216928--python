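"""Model skill scoring: RMSE for training fit, CV for validation skill.

The validation statistic is the coefficient of variation of the model
error,

    CV = RMSE(y, yhat) / mean(y),

i.e. root-mean-square prediction error scaled by the mean of the
measured NDVI series (dividing by the mean, not a standard deviation —
the statistic is implemented literally in this form).  A pixel model
with CV < 15% counts as good; CV >= 15% (boundary included) is poor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pixel_model import FitReport, PixelModel, predict_pixel
from .preprocess import PixelDataset, window_series

__all__ = [
    "ValidationReport",
    "GridSummary",
    "rmse",
    "cv",
    "classify_quality",
    "validate_pixel",
    "validate_grid",
    "grid_summary",
    "CV_THRESHOLD",
]

logger = logging.getLogger(__name__)

CV_THRESHOLD = 0.15
RMSE_THRESHOLD = 0.01


def rmse(measured, predicted) -> float:
    """Root mean squared difference between two aligned series."""
    y = np.asarray(measured, dtype=float)
    yh = np.asarray(predicted, dtype=float)
    if y.shape != yh.shape or y.ndim != 1 or y.size < 1:
        raise ValueError("measured and predicted must be equal-length 1-D series")
    if not (np.isfinite(y).all() and np.isfinite(yh).all()):
        raise ValueError("series contain non-finite values")
    return float(np.sqrt(np.mean((y - yh) ** 2)))


def cv(measured, predicted) -> float:
    """Error coefficient of variation: RMSE divided by the measured mean."""
    m = float(np.mean(np.asarray(measured, dtype=float)))
    if m == 0.0:
        raise ZeroDivisionError("CV undefined: mean of measured series is zero")
    return rmse(measured, predicted) / m


def classify_quality(cv_value: float) -> str:
    """'good' iff CV < 0.15; the boundary itself maps to 'poor'."""
    if not np.isfinite(cv_value) or cv_value < 0:
        raise ValueError(f"cv must be a finite non-negative number, got {cv_value}")
    return "good" if cv_value < CV_THRESHOLD else "poor"


@dataclass
class ValidationReport:
    """Validation-split skill of one pixel model."""

    pixel_id: int
    cv: float
    rmse_val: float
    quality: str
    predicted_series: np.ndarray = field(repr=False)
    measured_series: np.ndarray = field(repr=False)


def validate_pixel(model: PixelModel, ds: PixelDataset) -> ValidationReport:
    """Predict the validation months once each and score them."""
    _, val = window_series(ds)
    pred = predict_pixel(model, val)
    measured = ds.ndvi[ds.train_months :]
    c = cv(measured, pred)
    return ValidationReport(
        pixel_id=ds.pixel_id,
        cv=c,
        rmse_val=rmse(measured, pred),
        quality=classify_quality(c),
        predicted_series=pred,
        measured_series=measured.copy(),
    )


def validate_grid(
    results: dict[int, tuple[PixelModel, FitReport]],
    datasets: list[PixelDataset],
) -> list[ValidationReport]:
    """Score every fitted pixel; pixels with undefined CV are skipped with a warning."""
    by_id = {d.pixel_id: d for d in datasets}
    reports = []
    for pid, (model, _) in sorted(results.items()):
        try:
            reports.append(validate_pixel(model, by_id[pid]))
        except ZeroDivisionError:
            logger.warning("pixel %d excluded: mean measured NDVI is zero", pid)
    return reports


@dataclass
class GridSummary:
    """Grid-level skill fractions under the configured thresholds."""

    n_pixels: int
    rmse_threshold: float
    cv_threshold: float
    fraction_rmse_below: float
    fraction_cv_below: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def grid_summary(
    fits: list[FitReport],
    vals: list[ValidationReport],
    rmse_threshold: float = RMSE_THRESHOLD,
    cv_threshold: float = CV_THRESHOLD,
) -> GridSummary:
    """Fractions of pixels under the RMSE (training) and CV (validation) thresholds."""
    if not fits or not vals:
        raise ValueError("empty fit or validation collection")
    fr = float(np.mean([f.train_rmse < rmse_threshold for f in fits]))
    fc = float(np.mean([v.cv < cv_threshold for v in vals]))
    return GridSummary(
        n_pixels=len(vals),
        rmse_threshold=rmse_threshold,
        cv_threshold=cv_threshold,
        fraction_rmse_below=fr,
        fraction_cv_below=fc,
    )


def validation_frame(vals: list[ValidationReport]) -> pd.DataFrame:
    """ValidationReports as a tidy frame (pixel_id, cv, rmse_val, quality)."""
    return pd.DataFrame(
        {
            "pixel_id": [v.pixel_id for v in vals],
            "cv": [v.cv for v in vals],
            "rmse_val": [v.rmse_val for v in vals],
            "quality": [v.quality for v in vals],
        }
    )
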