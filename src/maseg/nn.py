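"""Minimal NumPy building blocks for the encoder–decoder network.

A deliberately small, dependency-free layer zoo — 3×3/1×1 convolutions via
``sliding_window_view`` im2col, ReLU, 2×2 max pooling, nearest-neighbor
upsampling and channel concatenation — each with an explicit ``backward``.
Arrays are NCHW.  This is enough to express the 5-level U-shaped
segmentation network and train it with Adam on CPU at test scale.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


class Conv2d:
    """Same-padded 2-D convolution (correlation), kernel 3 or 1."""

    def __init__(self, cin: int, cout: int, kernel: int, rng: np.random.Generator):
        assert kernel in (1, 3)
        self.kernel = kernel
        fan_in = cin * kernel * kernel
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cout, cin, kernel, kernel))
        self.w = Param(w.astype(np.float64))
        self.b = Param(np.zeros(cout, dtype=np.float64))
        self._xp: np.ndarray | None = None

    @property
    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        k = self.kernel
        if k == 1:
            self._xp = x
            out = np.tensordot(x, self.w.value[:, :, 0, 0], axes=([1], [1]))
            return np.ascontiguousarray(out.transpose(0, 3, 1, 2)) + self.b.value[None, :, None, None]
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        self._xp = xp
        cols = sliding_window_view(xp, (k, k), axis=(2, 3))  # (B,C,H,W,k,k)
        out = np.tensordot(cols, self.w.value, axes=([1, 4, 5], [1, 2, 3]))
        return np.ascontiguousarray(out.transpose(0, 3, 1, 2)) + self.b.value[None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        k = self.kernel
        self.b.grad += dout.sum(axis=(0, 2, 3))
        if k == 1:
            x = self._xp
            self.w.grad[:, :, 0, 0] += np.tensordot(dout, x, axes=([0, 2, 3], [0, 2, 3]))
            dx = np.tensordot(dout, self.w.value[:, :, 0, 0], axes=([1], [0]))
            return np.ascontiguousarray(dx.transpose(0, 3, 1, 2))
        cols = sliding_window_view(self._xp, (k, k), axis=(2, 3))
        self.w.grad += np.tensordot(dout, cols, axes=([0, 2, 3], [0, 2, 3]))
        dp = np.pad(dout, ((0, 0), (0, 0), (1, 1), (1, 1)))
        dcols = sliding_window_view(dp, (k, k), axis=(2, 3))  # (B,Co,H,W,k,k)
        wf = self.w.value[:, :, ::-1, ::-1]
        dx = np.tensordot(dcols, wf, axes=([1, 4, 5], [0, 2, 3]))
        return np.ascontiguousarray(dx.transpose(0, 3, 1, 2))


class ReLU:
    params: list = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class MaxPool2:
    """2×2 max pooling, stride 2; ties share the gradient equally."""

    params: list = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, h, w = x.shape
        xr = x.reshape(b, c, h // 2, 2, w // 2, 2)
        out = xr.max(axis=(3, 5))
        m = out[:, :, :, None, :, None]
        mask = (xr == m).astype(np.float64)
        mask /= mask.sum(axis=(3, 5), keepdims=True)
        self._mask = mask
        self._shape = x.shape
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        g = dout[:, :, :, None, :, None] * self._mask
        return g.reshape(self._shape)


class Upsample2:
    """Nearest-neighbor ×2 upsampling."""

    params: list = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, c, h, w = dout.shape
        return dout.reshape(b, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class ConvBlock:
    """Two 3×3 convolutions, each followed by ReLU."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.layers = [Conv2d(cin, cout, 3, rng), ReLU(), Conv2d(cout, cout, 3, rng), ReLU()]

    @property
    def params(self) -> list[Param]:
        return [p for lay in self.layers for p in lay.params]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for lay in self.layers:
            x = lay.forward(x)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for lay in reversed(self.layers):
            dout = lay.backward(dout)
        return dout


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class Adam:
    """Adam with decoupled-from-nothing classic L2 weight decay on gradients."""

    def __init__(self, params: list[Param], lr: float, weight_decay: float = 0.0,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.weight_decay = weight_decay
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.value
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class PlateauScheduler:
    """Multiply the learning rate by ``factor`` after ``patience`` epochs
    without improvement of the monitored (validation) loss."""

    def __init__(self, optimizer: Adam, patience: int = 5, factor: float = 0.1,
                 min_lr: float = 1e-8):
        self.opt = optimizer
        self.patience = patience
        self.factor = factor
        self.min_lr = min_lr
        self.best = np.inf
        self.stale = 0

    def step(self, val_loss: float) -> bool:
        """Record one epoch's validation loss; returns True if lr was reduced."""
        if val_loss < self.best - 1e-12:
            self.best = val_loss
            self.stale = 0
            return False
        self.stale += 1
        if self.stale >= self.patience:
            self.opt.lr = max(self.min_lr, self.opt.lr * self.factor)
            self.stale = 0
            return True
        return False
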