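"""A compact NumPy convolutional network for scalar regression.

Architecture (fixed topology, three tunable hyperparameters):

    3 x [ conv2D (same padding) -> relu -> maxpool 2x2 ]
    flatten -> dropout -> dense -> tanh -> dense(1)

trained with the adadelta optimizer on a mean-squared-error loss.  The
tunable hyperparameters are the (square, odd) convolutional filter size,
the dropout rate, and the number of training epochs.

Implementation notes: convolutions run via im2col matrix products;
max-pooling stores argmax indices for exact gradient routing; dropout is
inverted (activations rescaled at train time so inference needs no
correction).  Targets are z-scored internally during training and
predictions un-scaled, which keeps adadelta's unit-free updates well
conditioned regardless of the label scale.  All randomness (weight
initialization, batch shuffling, dropout masks) flows from one seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


@dataclass
class CnnSpec:
    """Hyperparameters of the regression CNN."""

    filter_size: int = 3          # square, odd
    dropout_rate: float = 0.25
    epochs: int = 20
    n_filters: tuple[int, int, int] = (8, 8, 8)
    hidden: int = 16
    batch_size: int = 16

    def validate(self) -> None:
        if self.filter_size % 2 != 1 or self.filter_size < 1:
            raise ValueError("filter_size must be odd and positive")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")

    def as_tuple(self) -> tuple:
        return (self.filter_size, self.dropout_rate, self.epochs)


def _im2col(x: np.ndarray, f: int) -> np.ndarray:
    """(N,H,W,C) -> (N,H,W,f*f*C) patches with same padding."""
    pad = f // 2
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
    win = sliding_window_view(xp, (f, f), axis=(1, 2))  # (N,H,W,C,f,f)
    n, h, w = x.shape[0], x.shape[1], x.shape[2]
    return win.transpose(0, 1, 2, 4, 5, 3).reshape(n, h, w, -1)


def _col2im(dcols: np.ndarray, shape: tuple, f: int) -> np.ndarray:
    """Adjoint of _im2col: scatter-add patch gradients back to the image."""
    n, h, w, c = shape
    pad = f // 2
    dxp = np.zeros((n, h + 2 * pad, w + 2 * pad, c))
    d = dcols.reshape(n, h, w, f, f, c)
    for p in range(f):
        for q in range(f):
            dxp[:, p : p + h, q : q + w, :] += d[:, :, :, p, q, :]
    return dxp[:, pad : pad + h, pad : pad + w, :]


class _Adadelta:
    """Per-parameter adadelta state (rho=0.95, eps=1e-6, no learning rate)."""

    def __init__(self, params: list[np.ndarray], rho: float = 0.95, eps: float = 1e-6):
        self.rho, self.eps = rho, eps
        self.eg = [np.zeros_like(p) for p in params]
        self.ed = [np.zeros_like(p) for p in params]

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        for i, (p, g) in enumerate(zip(params, grads)):
            self.eg[i] = self.rho * self.eg[i] + (1 - self.rho) * g**2
            delta = -np.sqrt(self.ed[i] + self.eps) / np.sqrt(self.eg[i] + self.eps) * g
            self.ed[i] = self.rho * self.ed[i] + (1 - self.rho) * delta**2
            p += delta


class CnnRegressor:
    """Three conv/pool blocks, flatten, dropout, dense-tanh-dense(1)."""

    def __init__(self, spec: CnnSpec, input_shape: tuple[int, int], seed: int = 0):
        spec.validate()
        self.spec = spec
        self.input_shape = input_shape
        self.rng = np.random.default_rng(seed)
        f = spec.filter_size
        h, w = input_shape
        chans = (1,) + spec.n_filters
        self.params: list[np.ndarray] = []
        self._conv_idx = []
        for b in range(3):
            fan_in = f * f * chans[b]
            wgt = self.rng.normal(0, np.sqrt(2.0 / fan_in), (fan_in, chans[b + 1]))
            bias = np.zeros(chans[b + 1])
            self._conv_idx.append(len(self.params))
            self.params += [wgt, bias]
            h, w = h // 2, w // 2
            if h < 1 or w < 1:
                raise ValueError("input image too small for 3 pooling stages")
        flat = h * w * chans[-1]
        lim1 = np.sqrt(6.0 / (flat + spec.hidden))
        self._dense_idx = len(self.params)
        self.params += [
            self.rng.uniform(-lim1, lim1, (flat, spec.hidden)),
            np.zeros(spec.hidden),
        ]
        lim2 = np.sqrt(6.0 / (spec.hidden + 1))
        self.params += [
            self.rng.uniform(-lim2, lim2, (spec.hidden, 1)),
            np.zeros(1),
        ]
        self._opt = _Adadelta(self.params)
        self._y_mu, self._y_sd = 0.0, 1.0

    # ---- forward / backward -------------------------------------------------

    def _forward(self, x: np.ndarray, train: bool) -> tuple[np.ndarray, dict]:
        f = self.spec.filter_size
        cache: dict = {"blocks": []}
        a = x
        for b in range(3):
            wi = self._conv_idx[b]
            cols = _im2col(a, f)
            z = cols @ self.params[wi] + self.params[wi + 1]
            relu = np.maximum(z, 0)
            n, h, w, c = relu.shape
            h2, w2 = h // 2, w // 2
            r = relu[:, : h2 * 2, : w2 * 2, :].reshape(n, h2, 2, w2, 2, c)
            r = r.transpose(0, 1, 3, 2, 4, 5).reshape(n, h2, w2, 4, c)
            arg = np.argmax(r, axis=3)
            pooled = np.take_along_axis(r, arg[:, :, :, None, :], axis=3)[:, :, :, 0, :]
            cache["blocks"].append(
                {"cols": cols, "z": z, "in_shape": a.shape, "arg": arg,
                 "relu_shape": relu.shape}
            )
            a = pooled
        n = a.shape[0]
        flat = a.reshape(n, -1)
        if train and self.spec.dropout_rate > 0:
            keep = 1.0 - self.spec.dropout_rate
            mask = (self.rng.random(flat.shape) < keep) / keep
        else:
            mask = np.ones_like(flat)
        dropped = flat * mask
        di = self._dense_idx
        h1 = dropped @ self.params[di] + self.params[di + 1]
        t1 = np.tanh(h1)
        out = t1 @ self.params[di + 2] + self.params[di + 3]
        cache.update(flat=flat, mask=mask, dropped=dropped, t1=t1,
                     pooled_shape=a.shape)
        return out[:, 0], cache

    def _backward(self, dout: np.ndarray, cache: dict) -> list[np.ndarray]:
        f = self.spec.filter_size
        di = self._dense_idx
        grads = [np.zeros_like(p) for p in self.params]
        d = dout[:, None]  # (N,1)
        grads[di + 2] = cache["t1"].T @ d
        grads[di + 3] = d.sum(axis=0)
        dt1 = d @ self.params[di + 2].T
        dh1 = dt1 * (1 - cache["t1"] ** 2)
        grads[di] = cache["dropped"].T @ dh1
        grads[di + 1] = dh1.sum(axis=0)
        dflat = (dh1 @ self.params[di].T) * cache["mask"]
        da = dflat.reshape(cache["pooled_shape"])
        for b in reversed(range(3)):
            blk = cache["blocks"][b]
            wi = self._conv_idx[b]
            n, h, w, c = blk["relu_shape"]
            h2, w2 = h // 2, w // 2
            dr = np.zeros((n, h2, w2, 4, c))
            np.put_along_axis(dr, blk["arg"][:, :, :, None, :], da[:, :, :, None, :], axis=3)
            drelu = np.zeros((n, h, w, c))
            drelu[:, : h2 * 2, : w2 * 2, :] = (
                dr.reshape(n, h2, w2, 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
                .reshape(n, h2 * 2, w2 * 2, c)
            )
            dz = drelu * (blk["z"] > 0)
            dz2 = dz.reshape(-1, c)
            cols2 = blk["cols"].reshape(-1, blk["cols"].shape[-1])
            grads[wi] = cols2.T @ dz2
            grads[wi + 1] = dz2.sum(axis=0)
            dcols = dz2 @ self.params[wi].T
            da = _col2im(dcols.reshape(dz.shape[:3] + (-1,)), blk["in_shape"], f)
        return grads

    # ---- public API ---------------------------------------------------------

    def fit(self, images: np.ndarray, y: np.ndarray) -> "CnnRegressor":
        """Train on (N, H, W) images and scalar targets."""
        x = np.asarray(images, dtype=float)[..., None]
        y = np.asarray(y, dtype=float)
        self._y_mu = float(y.mean())
        self._y_sd = float(y.std()) or 1.0
        yt = (y - self._y_mu) / self._y_sd
        n = len(y)
        bs = min(self.spec.batch_size, n)
        for _ in range(self.spec.epochs):
            order = self.rng.permutation(n)
            for start in range(0, n, bs):
                idx = order[start : start + bs]
                pred, cache = self._forward(x[idx], train=True)
                dout = 2.0 * (pred - yt[idx]) / len(idx)
                grads = self._backward(dout, cache)
                self._opt.step(self.params, grads)
        return self

    def predict(self, images: np.ndarray) -> np.ndarray:
        x = np.asarray(images, dtype=float)[..., None]
        pred, _ = self._forward(x, train=False)
        return pred * self._y_sd + self._y_mu

    def train_loss(self, images: np.ndarray, y: np.ndarray) -> float:
        """Mean squared error on the given data (original label scale)."""
        p = self.predict(images)
        return float(np.mean((p - np.asarray(y, dtype=float)) ** 2))
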