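"""Minimal numpy neural-network core for the saturation forecasters.

Implements exactly what the training protocol needs and nothing more: a
fully connected ReLU regressor, a single-layer GRU regressor, an Adam
optimizer, and a mini-batch training loop with patience-based early
stopping on an explicit validation set (MSE monitored, best weights
restored). All randomness flows through a caller-supplied Generator, so
training is bit-reproducible under a fixed seed. Gradients are exact
(checked against finite differences in the test suite).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["MLPNet", "GRUNet", "Adam", "TrainResult", "train_network"]


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class MLPNet:
    """Fully connected regressor: hidden ReLU layers, linear scalar output."""

    def __init__(self, n_inputs: int, hidden: Sequence[int], rng: np.random.Generator):
        if not hidden:
            raise ValueError("hidden layer spec must be non-empty")
        widths = [n_inputs, *hidden, 1]
        self.params: list[np.ndarray] = []
        for fan_in, fan_out in zip(widths[:-1], widths[1:]):
            # He initialization, appropriate for ReLU hidden units
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out))
            self.params.append(w)
            self.params.append(np.zeros(fan_out))
        self.n_inputs = n_inputs
        self.hidden = tuple(int(h) for h in hidden)

    def forward(self, X: np.ndarray) -> np.ndarray:
        a = X
        self._cache = [a]
        n_layers = len(self.params) // 2
        for li in range(n_layers):
            w, b = self.params[2 * li], self.params[2 * li + 1]
            z = a @ w + b
            a = z if li == n_layers - 1 else _relu(z)
            self._cache.append(a)
        return a[:, 0]

    def backward(self, dy: np.ndarray) -> list[np.ndarray]:
        """Gradients w.r.t. params given dLoss/dOutput; call after forward."""
        grads = [np.zeros_like(p) for p in self.params]
        n_layers = len(self.params) // 2
        delta = dy[:, None]
        for li in reversed(range(n_layers)):
            a_prev = self._cache[li]
            grads[2 * li] = a_prev.T @ delta
            grads[2 * li + 1] = delta.sum(axis=0)
            if li > 0:
                w = self.params[2 * li]
                delta = (delta @ w.T) * (self._cache[li] > 0)
        return grads

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X)


class GRUNet:
    """Single-layer GRU over (n, timesteps, channels) with linear readout."""

    def __init__(self, n_channels: int, n_units: int, rng: np.random.Generator):
        c, h = n_channels, n_units
        s_x = np.sqrt(1.0 / max(c, 1))
        s_h = np.sqrt(1.0 / h)
        # params: Wx (c,3h) [r|z|g blocks], Whr, Whz, Whg (h,h), b (3h), Wo (h,1), bo (1)
        self.params = [
            rng.normal(0.0, s_x, size=(c, 3 * h)),
            rng.normal(0.0, s_h, size=(h, h)),
            rng.normal(0.0, s_h, size=(h, h)),
            rng.normal(0.0, s_h, size=(h, h)),
            np.zeros(3 * h),
            rng.normal(0.0, s_h, size=(h, 1)),
            np.zeros(1),
        ]
        self.n_channels = c
        self.n_units = h

    def forward(self, X: np.ndarray) -> np.ndarray:
        Wx, Whr, Whz, Whg, b, Wo, bo = self.params
        n, T, _ = X.shape
        h = self.n_units
        H = np.zeros((n, h))
        cache = []
        ax_all = X.reshape(n * T, -1) @ Wx
        ax_all = ax_all.reshape(n, T, 3 * h) + b
        for t in range(T):
            ar, az, ag = (
                ax_all[:, t, :h],
                ax_all[:, t, h : 2 * h],
                ax_all[:, t, 2 * h :],
            )
            r = _sigmoid(ar + H @ Whr)
            z = _sigmoid(az + H @ Whz)
            rh = r * H
            g = np.tanh(ag + rh @ Whg)
            H_new = (1.0 - z) * H + z * g
            cache.append((H, r, z, g, rh))
            H = H_new
        self._cache = (X, cache, H)
        return (H @ Wo + bo)[:, 0]

    def backward(self, dy: np.ndarray) -> list[np.ndarray]:
        Wx, Whr, Whz, Whg, b, Wo, bo = self.params
        X, cache, H_T = self._cache
        n, T, c = X.shape
        h = self.n_units
        gWx = np.zeros_like(Wx)
        gWhr = np.zeros_like(Whr)
        gWhz = np.zeros_like(Whz)
        gWhg = np.zeros_like(Whg)
        gb = np.zeros_like(b)
        gWo = H_T.T @ dy[:, None]
        gbo = np.array([dy.sum()])
        dH = dy[:, None] @ Wo.T
        for t in reversed(range(T)):
            H_prev, r, z, g, rh = cache[t]
            dz_pre = dH * (g - H_prev) * z * (1.0 - z)
            dg_pre = dH * z * (1.0 - g * g)
            drh = dg_pre @ Whg.T
            dr_pre = drh * H_prev * r * (1.0 - r)
            x_t = X[:, t, :]
            gWx[:, :h] += x_t.T @ dr_pre
            gWx[:, h : 2 * h] += x_t.T @ dz_pre
            gWx[:, 2 * h :] += x_t.T @ dg_pre
            gWhr += H_prev.T @ dr_pre
            gWhz += H_prev.T @ dz_pre
            gWhg += rh.T @ dg_pre
            gb[:h] += dr_pre.sum(axis=0)
            gb[h : 2 * h] += dz_pre.sum(axis=0)
            gb[2 * h :] += dg_pre.sum(axis=0)
            dH = (
                dH * (1.0 - z)
                + drh * r
                + dr_pre @ Whr.T
                + dz_pre @ Whz.T
            )
        return [gWx, gWhr, gWhz, gWhg, gb, gWo, gbo]

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X)


class Adam:
    """Adam with the conventional defaults (lr 1e-3, betas 0.9/0.999)."""

    def __init__(
        self,
        params: list[np.ndarray],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


@dataclass
class TrainResult:
    best_val_mse: float
    epochs_run: int
    history: list[float] = field(default_factory=list)


def train_network(
    net,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    rng: np.random.Generator,
    *,
    lr: float = 1e-3,
    batch_size: int = 32,
    max_epochs: int = 200,
    patience: int = 10,
) -> TrainResult:
    """Mini-batch MSE training with early stopping on validation MSE.

    Stops once validation MSE has not improved for ``patience`` consecutive
    epochs (or at ``max_epochs``) and restores the best-epoch weights.
    """
    n = X_train.shape[0]
    opt = Adam(net.params, lr=lr)
    best_val = np.inf
    best_weights = [p.copy() for p in net.params]
    stall = 0
    history: list[float] = []
    epochs = 0
    for epoch in range(max_epochs):
        epochs = epoch + 1
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            yhat = net.forward(X_train[idx])
            resid = yhat - y_train[idx]
            dy = 2.0 * resid / idx.size
            grads = net.backward(dy)
            opt.step(net.params, grads)
        val_pred = net.forward(X_val)
        val_mse = float(np.mean((val_pred - y_val) ** 2))
        history.append(val_mse)
        if val_mse < best_val - 1e-12:
            best_val = val_mse
            best_weights = [p.copy() for p in net.params]
            stall = 0
        else:
            stall += 1
            if stall >= patience:
                break
    for p, w in zip(net.params, best_weights):
        p[...] = w
    return TrainResult(best_val_mse=best_val, epochs_run=epochs, history=history)
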