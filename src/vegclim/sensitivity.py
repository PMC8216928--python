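"""Permutation-importance sensitivity of the pixel models.

For a trained pixel model, the permutation importance (PI) of a feature
is the increase in validation MSE when that feature's monthly values are
randomly permuted across the whole validation period while the other
feature is left untouched:

    PI = mean_k( MSE(permuted_k) ) - MSE(baseline)

averaged over seeded permutation repeats.  Permutation is applied on the
reconstructed monthly series (the validation windows tile the split, so
the series round-trips exactly) and the shuffled series is re-windowed;
shuffling inside individual windows would preserve too much temporal
structure.  PI is on the MSE scale (NDVI^2 units) so that "larger =
more important" and the classification threshold has a concrete unit.

PIT and PIP are the importances of temperature and precipitation;
their difference PID = PIT - PIP classifies each pixel:
temperature-sensitive when PID >= 0.01, precipitation-sensitive when
PID <= -0.01, sensitive to both in between (boundaries inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from .pixel_model import PixelModel
from .preprocess import PixelDataset, WindowedSamples, window_series

__all__ = [
    "SensitivityResult",
    "PID_THRESHOLD",
    "FEATURES",
    "permutation_importance",
    "classify_pid",
    "sensitivity_grid",
    "biome_sensitivity",
]

PID_THRESHOLD = 0.01
FEATURES = ("temperature", "precipitation")
_FEATURE_CHANNEL = {"temperature": 0, "precipitation": 1}


@dataclass
class SensitivityResult:
    """Per-pixel permutation importances and the three-way class."""

    pixel_id: int
    pit: float
    pip: float
    pid: float
    sens_class: str
    n_repeats: int
    pit_sd: float
    pip_sd: float


def _windows_to_series(x: np.ndarray) -> np.ndarray:
    """(n_win, window, C) exactly tiling windows -> (n_win*window, C)."""
    return x.reshape(-1, x.shape[-1])


def _series_to_windows(s: np.ndarray, window: int) -> np.ndarray:
    return s.reshape(-1, window, s.shape[-1])


def permutation_importance(
    model: PixelModel,
    val: WindowedSamples,
    feature: str,
    n_repeats: int = 10,
    seed: int = 0,
) -> tuple[float, float]:
    """PI of one feature on the validation split; returns (PI, repeat sd)."""
    if feature not in _FEATURE_CHANNEL:
        raise ValueError(f"unknown feature {feature!r}; expected one of {FEATURES}")
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    if not val.tiles_exactly():
        raise ValueError("validation windows must tile the split (stride == window)")
    ch = _FEATURE_CHANNEL[feature]
    y = val.y
    base_mse = float(np.mean((model.predict_windows(val.x) - y) ** 2))
    series = _windows_to_series(val.x)
    n_months = series.shape[0]
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 17, ch]))
    errors = np.empty(n_repeats)
    for k in range(n_repeats):
        perm = rng.permutation(n_months)
        shuffled = series.copy()
        shuffled[:, ch] = series[perm, ch]
        xk = _series_to_windows(shuffled, val.window)
        errors[k] = np.mean((model.predict_windows(xk) - y) ** 2)
    pi = float(errors.mean() - base_mse)
    sd = float(errors.std(ddof=1)) if n_repeats > 1 else 0.0
    return pi, sd


def classify_pid(pit: float, pip: float, threshold: float = PID_THRESHOLD) -> tuple[float, str]:
    """PID = PIT - PIP and its three-way class (boundaries inclusive)."""
    if not (np.isfinite(pit) and np.isfinite(pip)):
        raise ValueError("pit and pip must be finite")
    pid = pit - pip
    if pid >= threshold:
        label = "temperature"
    elif pid <= -threshold:
        label = "precipitation"
    else:
        label = "both"
    return pid, label


def sensitivity_grid(
    results: dict[int, tuple[PixelModel, object]],
    datasets: list[PixelDataset],
    n_repeats: int = 10,
    seed: int = 0,
    threshold: float = PID_THRESHOLD,
) -> pd.DataFrame:
    """Per-pixel PIT/PIP/PID and sensitivity class for every fitted pixel."""
    by_id = {d.pixel_id: d for d in datasets}
    rows = []
    for pid_, (model, _) in sorted(results.items()):
        _, val = window_series(by_id[pid_])
        pixel_seed = int(np.random.SeedSequence([int(seed), 23, int(pid_)]).generate_state(1)[0] % (2**31))
        pit, pit_sd = permutation_importance(model, val, "temperature", n_repeats, pixel_seed)
        pip, pip_sd = permutation_importance(model, val, "precipitation", n_repeats, pixel_seed)
        pid, label = classify_pid(pit, pip, threshold)
        rows.append(
            {
                "pixel_id": pid_,
                "pit": pit,
                "pip": pip,
                "pid": pid,
                "sens_class": label,
                "n_repeats": n_repeats,
                "pit_sd": pit_sd,
                "pip_sd": pip_sd,
            }
        )
    return pd.DataFrame(rows)


def biome_sensitivity(results: pd.DataFrame, landcover: xr.DataArray) -> pd.DataFrame:
    """Aggregate sensitivity by dominant land-cover class.

    ``results`` is the frame from :func:`sensitivity_grid`; pixel ids are
    row-major indices into the coarse ``landcover`` grid.  Classes with
    no pixels are omitted; per-class sensitivity-class fractions sum to 1.
    """
    codes_flat = landcover.values.reshape(-1)
    scheme = landcover.attrs.get("scheme_size", 17)
    if ((codes_flat < 1) | (codes_flat > scheme)).any():
        raise ValueError(f"land-cover codes outside scheme 1..{scheme}")
    df = results.copy()
    if (df["pixel_id"] >= codes_flat.size).any():
        raise ValueError("pixel_id outside the land-cover grid")
    df["landcover_code"] = codes_flat[df["pixel_id"].values]
    out_rows = []
    for code, grp in df.groupby("landcover_code"):
        fr = grp["sens_class"].value_counts(normalize=True)
        out_rows.append(
            {
                "landcover_code": int(code),
                "n_pixels": len(grp),
                "mean_pit": grp["pit"].mean(),
                "mean_pip": grp["pip"].mean(),
                "mean_pid": grp["pid"].mean(),
                "frac_temperature": float(fr.get("temperature", 0.0)),
                "frac_precipitation": float(fr.get("precipitation", 0.0)),
                "frac_both": float(fr.get("both", 0.0)),
            }
        )
    return pd.DataFrame(out_rows).sort_values("landcover_code").reset_index(drop=True)
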