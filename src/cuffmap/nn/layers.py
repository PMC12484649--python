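"""Minimal NumPy neural-network layers with hand-written backprop.

Only what the MAP estimator needs: dilated causal 1-D convolution,
ReLU, inverted dropout, trailing-window average pooling, a (possibly
stacked) LSTM, a per-timestep affine head, and Adam.  Every layer
follows the same protocol::

    y = layer.forward(x, train=...)   # caches what backward needs
    dx = layer.backward(dy)           # accumulates into layer.grads

Parameters and gradients are exposed as aligned lists of arrays so an
optimizer can update them in place.  All arithmetic is float32 by
default (float64 available for gradient checking).

The convolution is evaluated as one im2col matrix product per batch,
which keeps the arithmetic inside BLAS; the column matrix is rebuilt
during the backward pass instead of cached, trading a little compute
for a much smaller memory footprint on long waveform segments.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "CausalConv1d",
    "ReLU",
    "Dropout",
    "TrailingAvgPool",
    "LSTM",
    "TimeDistributedAffine",
    "Adam",
]


class Layer:
    """Base: parameterless layers reuse these empty param/grad lists."""

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def zero_grads(self) -> None:
        for g in self.grads():
            g[...] = 0.0


def _glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int, dtype):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class CausalConv1d(Layer):
    """Dilated causal convolution: output at t sees inputs at t' <= t.

    Left pad of (k - 1) * dilation zeros enforces causality; stride is 1.
    Input/output layout is (batch, channels, time).
    """

    def __init__(self, c_in: int, c_out: int, kernel_size: int, dilation: int,
                 rng: np.random.Generator, dtype=np.float32):
        self.c_in, self.c_out = c_in, c_out
        self.k, self.dilation = kernel_size, dilation
        self.pad = (kernel_size - 1) * dilation
        self.dtype = dtype
        # weight per tap: w[j] maps input channels to output channels for
        # the sample lagged by (k - 1 - j) * dilation (tap k-1 = current)
        self.w = _glorot(rng, (kernel_size, c_out, c_in), c_in * kernel_size, c_out, dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._xp: np.ndarray | None = None

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]

    def _pad_left(self, x: np.ndarray) -> np.ndarray:
        b, c, t = x.shape
        xp = np.zeros((b, c, t + self.pad), dtype=x.dtype)
        xp[:, :, self.pad:] = x
        return xp

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        # one batched matmul per tap on strided views of the padded
        # input keeps the arithmetic in BLAS without im2col copies
        b, c, t = x.shape
        xp = self._pad_left(x)
        self._xp = xp
        y = np.empty((b, self.c_out, t), dtype=x.dtype)
        y[...] = self.b[None, :, None]
        d = self.dilation
        for j in range(self.k):
            y += np.matmul(self.w[j], xp[:, :, j * d: j * d + t])
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xp = self._xp
        b = xp.shape[0]
        t = xp.shape[2] - self.pad
        d = self.dilation
        self.db += dy.sum(axis=(0, 2))
        dxp = np.zeros_like(xp)
        for j in range(self.k):
            sl = slice(j * d, j * d + t)
            self.dw[j] += np.matmul(dy, xp[:, :, sl].transpose(0, 2, 1)).sum(axis=0)
            dxp[:, :, sl] += np.matmul(self.w[j].T, dy)
        return dxp[:, :, self.pad:]


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class Dropout(Layer):
    """Inverted dropout; identity at inference time."""

    def __init__(self, p: float, rng: np.random.Generator):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng = rng
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.p == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dy
        return dy * self._mask


class TrailingAvgPool(Layer):
    """Causal average pooling over trailing windows of ``factor`` samples
    at stride ``factor``: (B, C, T) -> (B, C, T // factor)."""

    def __init__(self, factor: int):
        self.factor = factor

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        b, c, t = x.shape
        if t % self.factor:
            raise ValueError(f"time axis {t} not a multiple of pool factor {self.factor}")
        self._shape = x.shape
        return x.reshape(b, c, t // self.factor, self.factor).mean(axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, c, t = self._shape
        out = np.repeat(dy[:, :, :, None], self.factor, axis=3) / self.factor
        return out.reshape(b, c, t).astype(dy.dtype)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


class LSTM(Layer):
    """Single LSTM layer over (B, T, D) with externally supplied h0, c0.

    Gate order: input, forget, cell, output.  A high ``forget_bias``
    starts the forget gate near 1 so the calibrated initial state is
    retained over long segments and its gradient does not vanish.
    """

    def __init__(self, d_in: int, d_hidden: int, rng: np.random.Generator,
                 dtype=np.float32, forget_bias: float = 1.0):
        self.d_in, self.d_hidden = d_in, d_hidden
        self.dtype = dtype
        h = d_hidden
        self.wx = _glorot(rng, (d_in, 4 * h), d_in, 4 * h, dtype)
        self.wh = _glorot(rng, (h, 4 * h), h, 4 * h, dtype)
        self.b = np.zeros(4 * h, dtype=dtype)
        self.b[h:2 * h] = forget_bias
        self.dwx = np.zeros_like(self.wx)
        self.dwh = np.zeros_like(self.wh)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.wx, self.wh, self.b]

    def grads(self):
        return [self.dwx, self.dwh, self.db]

    def forward(self, x: np.ndarray, h0: np.ndarray, c0: np.ndarray,
                train: bool = False) -> np.ndarray:
        b, t, d = x.shape
        h = self.d_hidden
        hs = np.empty((b, t, h), dtype=self.dtype)
        self._cache = []
        h_t, c_t = h0.astype(self.dtype), c0.astype(self.dtype)
        xw = x @ self.wx  # precompute input contributions for all steps
        for step in range(t):
            z = xw[:, step, :] + h_t @ self.wh + self.b
            i = _sigmoid(z[:, :h])
            f = _sigmoid(z[:, h:2 * h])
            g = np.tanh(z[:, 2 * h:3 * h])
            o = _sigmoid(z[:, 3 * h:])
            c_new = f * c_t + i * g
            tanh_c = np.tanh(c_new)
            h_new = o * tanh_c
            self._cache.append((h_t, c_t, i, f, g, o, tanh_c))
            h_t, c_t = h_new, c_new
            hs[:, step, :] = h_new
        self._x = x
        return hs

    def backward(self, dhs: np.ndarray) -> np.ndarray:
        x = self._x
        b, t, d = x.shape
        h = self.d_hidden
        dx = np.empty_like(x)
        dh_next = np.zeros((b, h), dtype=self.dtype)
        dc_next = np.zeros((b, h), dtype=self.dtype)
        for step in range(t - 1, -1, -1):
            h_prev, c_prev, i, f, g, o, tanh_c = self._cache[step]
            dh = dhs[:, step, :] + dh_next
            do = dh * tanh_c
            dc = dh * o * (1.0 - tanh_c ** 2) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g ** 2),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            self.dwx += x[:, step, :].T @ dz
            self.dwh += h_prev.T @ dz
            self.db += dz.sum(axis=0)
            dx[:, step, :] = dz @ self.wx.T
            dh_next = dz @ self.wh.T
            dc_next = dc * f
        return dx


class TimeDistributedAffine(Layer):
    """Pointwise affine head: (B, T, H) -> (B, T) regression output."""

    def __init__(self, d_in: int, rng: np.random.Generator, dtype=np.float32):
        self.w = _glorot(rng, (d_in,), d_in, 1, dtype)
        self.b = np.zeros(1, dtype=dtype)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.w + self.b[0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dw += np.einsum("bt,bth->h", dy, self._x, optimize=True)
        self.db += dy.sum(keepdims=True).reshape(1)
        return dy[:, :, None] * self.w[None, None, :]


class Adam:
    """Adam with optional global-norm gradient clipping."""

    def __init__(self, params: list[np.ndarray], grads: list[np.ndarray],
                 lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8, clip_norm: float | None = 5.0):
        self.params, self.grads_ = params, grads
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.clip_norm = clip_norm
        self.m = [np.zeros_like(p, dtype=np.float64) for p in params]
        self.v = [np.zeros_like(p, dtype=np.float64) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        gs = self.grads_
        if self.clip_norm is not None:
            total = np.sqrt(sum(float((g.astype(np.float64) ** 2).sum()) for g in gs))
            if total > self.clip_norm:
                scale = self.clip_norm / (total + 1e-12)
                gs = [g * scale for g in gs]
        b1c = 1.0 - self.beta1 ** self.t
        b2c = 1.0 - self.beta2 ** self.t
        for p, g, m, v in zip(self.params, gs, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * (g.astype(np.float64) ** 2)
            update = self.lr * (m / b1c) / (np.sqrt(v / b2c) + self.eps)
            p -= update.astype(p.dtype)
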