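"""Minimal deterministic stacked-LSTM regressor in numpy.

Implements exactly the topology the per-pixel models need — stacked LSTM
layers feeding a time-distributed dense head (sequence-to-sequence) —
with full backpropagation through time and an Adam optimizer.  Written
in numpy so training is single-threaded-deterministic and dependency-free.

Gate order inside the packed weight matrices is (input i, forget f,
output o, cell g), so one sigmoid call covers the first three gates.
Forget-gate biases are initialized to 1, other
parameters uniform in [-1/sqrt(H), 1/sqrt(H)] (the standard recurrent
init).  Gradients are exact; tests check them against central
differences.
"""

from __future__ import annotations

import numpy as np

__all__ = ["LSTMRegressor", "Adam", "mse_loss"]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    # numerically stable and vectorizes in one pass
    return 0.5 * (np.tanh(0.5 * x) + 1.0)


class LSTMRegressor:
    """Stacked LSTM + time-distributed dense head, (B, T, D) -> (B, T, out)."""

    def __init__(
        self,
        input_dim: int,
        hidden_dim: int,
        n_layers: int,
        output_dim: int,
        rng: np.random.Generator,
    ) -> None:
        if min(input_dim, hidden_dim, n_layers, output_dim) < 1:
            raise ValueError("all dimensions must be positive")
        self.input_dim = input_dim
        self.hidden_dim = hidden_dim
        self.n_layers = n_layers
        self.output_dim = output_dim
        H = hidden_dim
        k = 1.0 / np.sqrt(H)
        self.params: dict[str, np.ndarray] = {}
        for l in range(n_layers):
            d_in = input_dim if l == 0 else H
            self.params[f"Wx{l}"] = rng.uniform(-k, k, size=(d_in, 4 * H))
            self.params[f"Wh{l}"] = rng.uniform(-k, k, size=(H, 4 * H))
            b = rng.uniform(-k, k, size=4 * H)
            b[H : 2 * H] = 1.0  # forget gate bias
            self.params[f"b{l}"] = b
        self.params["Wy"] = rng.uniform(-k, k, size=(H, output_dim))
        self.params["by"] = rng.uniform(-k, k, size=output_dim)

    # -- forward ---------------------------------------------------------

    def forward(self, x: np.ndarray, cache: bool = False):
        """Run the network over a batch of windows.

        ``x`` is (B, T, input_dim).  Returns (B, T, output_dim) and,
        when ``cache`` is set, the intermediates needed for backward.
        """
        B, T, D = x.shape
        if D != self.input_dim:
            raise ValueError(f"expected input dim {self.input_dim}, got {D}")
        H = self.hidden_dim
        caches = []
        inp = x
        for l in range(self.n_layers):
            Wx, Wh, b = (
                self.params[f"Wx{l}"],
                self.params[f"Wh{l}"],
                self.params[f"b{l}"],
            )
            # input projection for all timesteps in one matmul
            zx = inp.reshape(B * T, -1) @ Wx
            zx = zx.reshape(B, T, 4 * H) + b
            h = np.zeros((B, H))
            c = np.zeros((B, H))
            hs = np.empty((B, T, H))
            layer_cache = []
            for t in range(T):
                z = zx[:, t] + h @ Wh
                sig = _sigmoid(z[:, : 3 * H])
                i = sig[:, :H]
                f = sig[:, H : 2 * H]
                o = sig[:, 2 * H :]
                g = np.tanh(z[:, 3 * H :])
                c_new = f * c + i * g
                tc = np.tanh(c_new)
                h_new = o * tc
                if cache:
                    layer_cache.append((h, c, i, f, g, o, c_new, tc))
                h, c = h_new, c_new
                hs[:, t] = h
            caches.append((layer_cache, inp))
            inp = hs
        y = inp @ self.params["Wy"] + self.params["by"]
        if cache:
            return y, (caches, inp)
        return y

    # -- backward --------------------------------------------------------

    def backward(self, dy: np.ndarray, cache) -> dict[str, np.ndarray]:
        """Exact gradients of a scalar loss given d(loss)/d(output)."""
        caches, top_h = cache
        B, T, _ = dy.shape
        H = self.hidden_dim
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        Wy = self.params["Wy"]
        grads["Wy"] = np.einsum("bth,bto->ho", top_h, dy)
        grads["by"] = dy.sum(axis=(0, 1))
        d_inp = dy @ Wy.T  # gradient wrt the top LSTM layer's hidden sequence

        for l in range(self.n_layers - 1, -1, -1):
            layer_cache, inp = caches[l]
            Wx, Wh = self.params[f"Wx{l}"], self.params[f"Wh{l}"]
            dWh = np.zeros_like(Wh)
            dz_all = np.empty((B, T, 4 * H))
            dh_next = np.zeros((B, H))
            dc_next = np.zeros((B, H))
            for t in range(T - 1, -1, -1):
                h_prev, c_prev, i, f, g, o, c_new, tc = layer_cache[t]
                dh = d_inp[:, t] + dh_next
                do = dh * tc
                dc = dh * o * (1 - tc * tc) + dc_next
                dc_next = dc * f
                dz = dz_all[:, t]
                dz[:, :H] = dc * g * i * (1 - i)
                dz[:, H : 2 * H] = dc * c_prev * f * (1 - f)
                dz[:, 2 * H : 3 * H] = do * o * (1 - o)
                dz[:, 3 * H :] = dc * i * (1 - g * g)
                dWh += h_prev.T @ dz
                dh_next = dz @ Wh.T
            dz_flat = dz_all.reshape(B * T, 4 * H)
            grads[f"Wx{l}"] = inp.reshape(B * T, -1).T @ dz_flat
            grads[f"Wh{l}"] = dWh
            grads[f"b{l}"] = dz_flat.sum(axis=0)
            d_inp = (dz_flat @ Wx.T).reshape(B, T, -1)
        return grads

    # -- state -----------------------------------------------------------

    def copy_params(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_params(self, params: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = params[k].copy()


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error over every element, and its gradient wrt pred."""
    diff = pred - target
    loss = float(np.mean(diff * diff))
    return loss, (2.0 / diff.size) * diff


class Adam:
    """Adam optimizer over a named parameter dict."""

    def __init__(
        self,
        params: dict[str, np.ndarray],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for k, p in params.items():
            g = grads[k]
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * (g * g)
            p -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)
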