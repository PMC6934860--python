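"""Minimal NHWC tensor layers with manual backprop.

Implements exactly what the spheroid segmenter needs — dilated 3x3
convolution, 1x1 convolution, ReLU, spatial dropout and Adam — in
float32 NumPy.  Convolutions are evaluated as nine shifted GEMMs (one
per kernel tap), which keeps memory flat and lets BLAS do the work;
the same trick runs the backward pass as nine slice-accumulations.

Tensors are (N, H, W, C) throughout.  All randomness flows through an
explicit ``numpy.random.Generator`` so that two builds or two training
runs from the same seed are bit-identical.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv2d", "ReLU", "Dropout", "Adam", "Sequential"]


class Layer:
    """Base class: a layer owns its parameters and their gradients."""

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2d(Layer):
    """2-D convolution with square kernel, 'same' zero padding and dilation.

    Kernel weights have shape (kh, kw, c_in, c_out); He-normal init.
    """

    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel_size: int = 3,
        dilation: int = 1,
        rng: np.random.Generator | None = None,
    ):
        if kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd for 'same' padding")
        rng = rng or np.random.default_rng(0)
        self.k = kernel_size
        self.dilation = dilation
        self.c_in = c_in
        self.c_out = c_out
        fan_in = kernel_size * kernel_size * c_in
        scale = np.sqrt(2.0 / fan_in)
        self.W = (rng.standard_normal((kernel_size, kernel_size, c_in, c_out)) * scale).astype(
            np.float32
        )
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._xp: np.ndarray | None = None

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    @property
    def pad(self) -> int:
        return (self.k // 2) * self.dilation

    def _im2col(self, xp: np.ndarray, n: int, h: int, w: int) -> np.ndarray:
        """(N, Hp, Wp, C) padded input -> (N*H*W, k*k*C) patch matrix."""
        d, k, c = self.dilation, self.k, self.c_in
        sn, sh, sw, sc = xp.strides
        win = np.lib.stride_tricks.as_strided(
            xp,
            shape=(n, h, w, k, k, c),
            strides=(sn, sh, sw, sh * d, sw * d, sc),
            writeable=False,
        )
        return np.ascontiguousarray(win).reshape(n * h * w, k * k * c)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        n, h, w, _ = x.shape
        p = self.pad
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0))) if p else x
        if self.k == 1:
            cols = np.ascontiguousarray(x).reshape(n * h * w, self.c_in)
        else:
            cols = self._im2col(xp, n, h, w)
        self._cols = cols if training else None
        self._shape = (n, h, w)
        out = cols @ self.W.reshape(-1, self.c_out) + self.b
        return out.reshape(n, h, w, self.c_out)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        assert self._cols is not None, "backward before training-mode forward"
        n, h, w = self._shape
        d, p, k, c = self.dilation, self.pad, self.k, self.c_in
        g = dout.reshape(-1, self.c_out)
        self.db[:] = g.sum(axis=0)
        self.dW[...] = (self._cols.T @ g).reshape(self.W.shape)
        dcols = (g @ self.W.reshape(-1, self.c_out).T).reshape(n, h, w, k, k, c)
        self._cols = None
        if k == 1:
            return dcols.reshape(n, h, w, c)
        dxp = np.zeros((n, h + 2 * p, w + 2 * p, c), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                dxp[:, i * d : i * d + h, j * d : j * d + w, :] += dcols[:, :, :, i, j, :]
        return dxp[:, p:-p, p:-p, :]


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        out = np.maximum(x, 0.0)
        self._mask = x > 0 if training else None
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class Dropout(Layer):
    """Inverted dropout; identity when rate == 0 or in eval mode."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dout
        return dout * self._mask


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def grads(self):
        return [g for l in self.layers for g in l.grads()]

    def forward(self, x, training):
        for l in self.layers:
            x = l.forward(x, training)
        return x

    def backward(self, dout):
        for l in reversed(self.layers):
            dout = l.backward(dout)
        return dout


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * np.square(g)
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
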