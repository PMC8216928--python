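"""Per-pixel sequence models: build, train, predict, and fit a whole grid.

One independent model per pixel, following the production design: two
cascading LSTM layers of dimension 75 and a dense head, mapping a
6-month window of (temperature, precipitation) to the 6 monthly NDVI
values of the same window (sequence-to-sequence).  Optimized with Adam
on MSE; training stops when the best epoch loss has not improved by more
than a small tolerance for ``patience`` epochs, and the best-loss
parameters are retained.

Everything is seeded: parameter initialization and batch shuffling per
pixel derive from the master seed and the pixel id, so a grid fit is
bit-reproducible in single-threaded mode.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .lstm import Adam, LSTMRegressor, mse_loss
from .preprocess import PixelDataset, WindowedSamples, window_series

__all__ = [
    "ModelConfig",
    "PixelModel",
    "FitReport",
    "DivergenceError",
    "build_model",
    "train_pixel",
    "predict_pixel",
    "fit_grid",
]

logger = logging.getLogger(__name__)


class DivergenceError(RuntimeError):
    """Training produced a non-finite loss."""


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of one pixel model.

    The architecture fields (two recurrent layers of 75 units, 2 input
    channels, 1 output, 6-month window) are the production topology;
    the optimization fields are conventional Adam settings with a
    plateau stop (no improvement of the best epoch loss by more than
    ``tol`` for ``patience`` epochs).
    """

    n_recurrent_layers: int = 2
    layer_dim: int = 75
    input_channels: int = 2
    output_channels: int = 1
    window: int = 6
    max_epochs: int = 300
    patience: int = 20
    tol: float = 1e-6
    learning_rate: float = 1e-3
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if min(
            self.n_recurrent_layers,
            self.layer_dim,
            self.input_channels,
            self.output_channels,
            self.window,
            self.max_epochs,
            self.batch_size,
        ) < 1:
            raise ValueError("model dimensions and budgets must be positive")


@dataclass
class PixelModel:
    """A (possibly trained) network for one pixel."""

    net: LSTMRegressor = field(repr=False)
    config: ModelConfig
    trained: bool = False

    def predict_windows(self, x: np.ndarray) -> np.ndarray:
        """(n, window, channels) -> (n, window) NDVI predictions."""
        return self.net.forward(x)[..., 0]


@dataclass
class FitReport:
    """Training diagnostics for one pixel."""

    pixel_id: int
    train_rmse: float
    loss_history: list[float] = field(repr=False)
    epochs_run: int
    converged: bool


def build_model(cfg: ModelConfig) -> PixelModel:
    """Untrained model with the configured topology, seeded initialization."""
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 97]))
    net = LSTMRegressor(
        cfg.input_channels,
        cfg.layer_dim,
        cfg.n_recurrent_layers,
        cfg.output_channels,
        rng,
    )
    return PixelModel(net=net, config=cfg)


def train_pixel(
    model: PixelModel, train: WindowedSamples, cfg: ModelConfig, pixel_id: int = -1
) -> FitReport:
    """Adam/MSE training with plateau stopping and best-loss checkpointing."""
    if train.n_windows < 1:
        raise ValueError("need at least one training window")
    x, y = train.x, train.y[..., None]
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 131, max(pixel_id, 0)]))
    opt = Adam(model.net.params, lr=cfg.learning_rate)
    best_loss = np.inf
    best_params = model.net.copy_params()
    stall = 0
    history: list[float] = []
    n = train.n_windows
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        total = 0.0
        for lo in range(0, n, cfg.batch_size):
            idx = order[lo : lo + cfg.batch_size]
            pred, cache = model.net.forward(x[idx], cache=True)
            loss, dy = mse_loss(pred, y[idx])
            if not np.isfinite(loss):
                raise DivergenceError(f"non-finite loss at pixel {pixel_id}, epoch {epoch}")
            grads = model.net.backward(dy, cache)
            opt.step(model.net.params, grads)
            total += loss * len(idx)
        epoch_loss = total / n
        history.append(epoch_loss)
        if epoch_loss < best_loss - cfg.tol:
            best_loss = epoch_loss
            best_params = model.net.copy_params()
            stall = 0
        else:
            stall += 1
            if stall >= cfg.patience:
                break
    model.net.set_params(best_params)
    model.trained = True
    pred = model.predict_windows(x)
    train_rmse = float(np.sqrt(np.mean((pred - train.y) ** 2)))
    return FitReport(
        pixel_id=pixel_id,
        train_rmse=train_rmse,
        loss_history=history,
        epochs_run=len(history),
        converged=len(history) < cfg.max_epochs,
    )


def predict_pixel(model: PixelModel, windows: WindowedSamples) -> np.ndarray:
    """Concatenated monthly predictions over an exactly tiling window set."""
    if not model.trained:
        raise RuntimeError("model has not been trained")
    if not windows.tiles_exactly():
        raise ValueError("windows must tile the split with stride == window")
    return model.predict_windows(windows.x).reshape(-1)


def _pixel_seed(master: int, pixel_id: int) -> int:
    ss = np.random.SeedSequence([int(master), 59, int(pixel_id)])
    return int(ss.generate_state(1)[0] % (2**31))


def fit_grid(
    datasets: list[PixelDataset],
    cfg: ModelConfig,
    train_stride: int = 1,
    progress: bool = False,
) -> dict[int, tuple[PixelModel, FitReport]]:
    """Train one independent model per pixel.

    Per-pixel seeds derive deterministically from ``cfg.seed`` and the
    pixel id; a diverging pixel is logged and skipped, never fatal.
    """
    if not datasets:
        raise ValueError("no pixel datasets to fit")
    results: dict[int, tuple[PixelModel, FitReport]] = {}
    for k, ds in enumerate(datasets):
        pcfg = ModelConfig(**{**asdict(cfg), "seed": _pixel_seed(cfg.seed, ds.pixel_id)})
        train, _ = window_series(ds, train_stride=train_stride)
        model = build_model(pcfg)
        try:
            report = train_pixel(model, train, pcfg, pixel_id=ds.pixel_id)
        except DivergenceError as exc:  # isolate the failure, keep the run alive
            logger.warning("pixel %d failed: %s", ds.pixel_id, exc)
            continue
        results[ds.pixel_id] = (model, report)
        if progress and (k + 1) % 10 == 0:
            logger.info("fitted %d/%d pixels", k + 1, len(datasets))
    return results


def reports_frame(results: dict[int, tuple[PixelModel, FitReport]]) -> pd.DataFrame:
    """FitReports as a tidy frame (pixel_id, train_rmse, epochs, converged)."""
    rows = [
        {
            "pixel_id": r.pixel_id,
            "train_rmse": r.train_rmse,
            "epochs_run": r.epochs_run,
            "converged": r.converged,
        }
        for _, r in results.values()
    ]
    return pd.DataFrame(rows).sort_values("pixel_id").reset_index(drop=True)


def load_models(models_dir) -> dict[int, PixelModel]:
    """Load per-pixel models saved by :func:`save_models`."""
    models_dir = Path(models_dir)
    manifest = json.loads((models_dir / "manifest.json").read_text())
    out: dict[int, PixelModel] = {}
    for pid, entry in manifest.items():
        cfg = ModelConfig(**entry["config"])
        model = build_model(cfg)
        with np.load(models_dir / entry["file"]) as npz:
            model.net.set_params(dict(npz))
        model.trained = True
        out[int(pid)] = model
    return out


def save_models(results: dict[int, tuple[PixelModel, FitReport]], out_dir) -> None:
    """Serialize per-pixel parameters (.npz) with a JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {}
    for pid, (model, _) in sorted(results.items()):
        fname = f"pixel_{pid:06d}.npz"
        np.savez(out / fname, **model.net.params)
        manifest[str(pid)] = {"file": fname, "config": asdict(model.config)}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
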