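"""Minimal NumPy neural-network primitives with hand-derived backprop.

Just enough machinery for the residual-encoder U-Net in :mod:`ctrseg.model`:
im2col convolutions, batch normalisation, ReLU, 2x2 max-pooling,
nearest-neighbour upsampling, and SGD with momentum.  All tensors are
``float32`` in NCHW layout.  Forward passes cache what backward needs, so a
layer instance handles one forward/backward pair at a time (standard
single-stream training).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DTYPE = np.float32


class Param:
    """A learnable array with its gradient and SGD velocity."""

    __slots__ = ("data", "grad", "vel")

    def __init__(self, data: np.ndarray):
        self.data = np.ascontiguousarray(data, dtype=DTYPE)
        self.grad = np.zeros_like(self.data)
        self.vel = np.zeros_like(self.data)


class Layer:
    def params(self) -> list[Param]:
        return []

    def buffers(self) -> list[np.ndarray]:
        """Non-learnable state (e.g. BN running stats), for checkpoints."""
        return []

    def set_buffers(self, arrays: list[np.ndarray]) -> None:
        pass


class Conv2d(Layer):
    """k x k convolution via im2col; 'same'-style zero padding by default."""

    def __init__(self, cin, cout, k, stride=1, pad=None, bias=True, rng=None):
        self.cin, self.cout, self.k, self.stride = cin, cout, k, stride
        self.pad = (k // 2) if pad is None else pad
        rng = rng or np.random.default_rng(0)
        fan_in = cin * k * k
        self.W = Param(rng.normal(0.0, np.sqrt(2.0 / fan_in), (cout, fan_in)))
        self.b = Param(np.zeros(cout)) if bias else None
        self._cache = None

    def params(self):
        return [self.W] + ([self.b] if self.b is not None else [])

    def forward(self, x, train=True):
        n, c, h, w = x.shape
        k, s, p = self.k, self.stride, self.pad
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        oh = (x.shape[2] - k) // s + 1
        ow = (x.shape[3] - k) // s + 1
        win = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            n * oh * ow, c * k * k
        )
        out = cols @ self.W.data.T
        if self.b is not None:
            out += self.b.data
        self._cache = (cols, (n, c, h, w), (oh, ow))
        return np.ascontiguousarray(
            out.reshape(n, oh, ow, self.cout).transpose(0, 3, 1, 2)
        )

    def backward(self, g):
        cols, (n, c, h, w), (oh, ow) = self._cache
        k, s, p = self.k, self.stride, self.pad
        gm = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(-1, self.cout)
        self.W.grad += gm.T @ cols
        if self.b is not None:
            self.b.grad += gm.sum(axis=0)
        dcols = (gm @ self.W.data).reshape(n, oh, ow, c, k, k)
        dcols = dcols.transpose(0, 3, 1, 2, 4, 5)  # (n, c, oh, ow, k, k)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=DTYPE)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + s * oh:s, j:j + s * ow:s] += dcols[..., i, j]
        self._cache = None
        return dxp[:, :, p:p + h, p:p + w] if p else dxp


class BatchNorm2d(Layer):
    """Batch normalisation.

    Evaluation statistics are a bias-corrected exponential moving average
    of the batch statistics (accumulators start at zero and are divided by
    1 − (1 − m)^n), so eval-mode outputs track the training distribution
    from the very first batches instead of being shrunk toward the
    zero-mean/unit-variance initialisation.
    """

    def __init__(self, c, eps=1e-5, momentum=0.1):
        self.eps, self.momentum = eps, momentum
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.ema_mean = np.zeros(c, dtype=DTYPE)
        self.ema_var = np.zeros(c, dtype=DTYPE)
        self.n_batches = np.zeros(1, dtype=np.int64)
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def buffers(self):
        return [self.ema_mean, self.ema_var, self.n_batches]

    def set_buffers(self, arrays):
        self.ema_mean = np.ascontiguousarray(arrays[0], dtype=DTYPE)
        self.ema_var = np.ascontiguousarray(arrays[1], dtype=DTYPE)
        self.n_batches = np.ascontiguousarray(arrays[2], dtype=np.int64)

    def running_stats(self):
        n = int(self.n_batches[0])
        if n == 0:
            return np.zeros_like(self.ema_mean), np.ones_like(self.ema_var)
        corr = 1.0 - (1.0 - self.momentum) ** n
        return self.ema_mean / corr, self.ema_var / corr

    def forward(self, x, train=True):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self.n_batches[0] += 1
            self.ema_mean = ((1 - m) * self.ema_mean + m * mean).astype(DTYPE)
            self.ema_var = ((1 - m) * self.ema_var + m * var).astype(DTYPE)
        else:
            mean, var = self.running_stats()
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[:, None, None]) * invstd[:, None, None]
        self._cache = (xhat, invstd) if train else None
        return (self.gamma.data[:, None, None] * xhat
                + self.beta.data[:, None, None]).astype(DTYPE)

    def backward(self, g):
        xhat, invstd = self._cache
        self._cache = None
        m = g.shape[0] * g.shape[2] * g.shape[3]
        self.gamma.grad += (g * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += g.sum(axis=(0, 2, 3))
        dxhat = g * self.gamma.data[:, None, None]
        t1 = dxhat.sum(axis=(0, 2, 3))
        t2 = (dxhat * xhat).sum(axis=(0, 2, 3))
        dx = (invstd[:, None, None] / m) * (
            m * dxhat - t1[:, None, None] - xhat * t2[:, None, None]
        )
        return dx.astype(DTYPE)


class ReLU(Layer):
    def forward(self, x, train=True):
        self._mask = x > 0
        return x * self._mask

    def backward(self, g):
        out = g * self._mask
        self._mask = None
        return out


class MaxPool2(Layer):
    """2x2 max pooling with stride 2 (spatial dims must be even)."""

    def forward(self, x, train=True):
        n, c, h, w = x.shape
        v = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        v = np.ascontiguousarray(v).reshape(n, c, h // 2, w // 2, 4)
        self._idx = v.argmax(axis=-1)
        self._shape = (n, c, h, w)
        return np.take_along_axis(v, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, g):
        n, c, h, w = self._shape
        dv = np.zeros((n, c, h // 2, w // 2, 4), dtype=DTYPE)
        np.put_along_axis(dv, self._idx[..., None], g[..., None], axis=-1)
        dv = dv.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        self._idx = None
        return np.ascontiguousarray(dv).reshape(n, c, h, w)


class Upsample2(Layer):
    """Nearest-neighbour 2x upsampling."""

    def forward(self, x, train=True):
        return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)

    def backward(self, g):
        n, c, h, w = g.shape
        return g.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5)).astype(DTYPE)


class SGD:
    """Stochastic gradient descent with classical momentum.

    Update: v <- momentum * v + grad;  w <- w - lr * v.
    """

    def __init__(self, params: list[Param], lr: float, momentum: float = 0.0):
        self.params = params
        self.lr = lr
        self.momentum = momentum

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        for p in self.params:
            p.vel *= self.momentum
            p.vel += p.grad
            p.data -= self.lr * p.vel


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_backward(probs: np.ndarray, dprobs: np.ndarray, axis: int = 1):
    """dL/dlogits from dL/dprobs for a softmax along ``axis``."""
    inner = (dprobs * probs).sum(axis=axis, keepdims=True)
    return (probs * (dprobs - inner)).astype(DTYPE)
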