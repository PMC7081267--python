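"""Minimal 3D convolutional layers on numpy, with hand-derived backprop.

Arrays are channels-last: ``(batch, D, H, W, C)`` in float32.  Convolutions
are evaluated as a sum of shifted GEMMs (one matrix product per kernel
offset), which keeps peak memory at one feature map per offset and routes
all heavy arithmetic through BLAS.
"""

from __future__ import annotations

import itertools

import numpy as np


class Layer:
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    @property
    def params(self) -> list[np.ndarray]:
        return []

    @property
    def grads(self) -> list[np.ndarray]:
        return []


class Conv3d(Layer):
    """Same-padded 3D convolution, cubic kernel, optional fused ReLU.

    Weights have shape ``(k, k, k, c_in, c_out)``; initialization is
    He-normal (fan-in) for ReLU layers and Glorot otherwise.
    """

    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: int = 3,
        relu: bool = True,
        rng: np.random.Generator | None = None,
        bias_init: float = 0.0,
    ):
        self.c_in, self.c_out, self.kernel, self.relu = c_in, c_out, kernel, relu
        rng = rng or np.random.default_rng(0)
        fan_in = kernel**3 * c_in
        if relu:
            scale = np.sqrt(2.0 / fan_in)
        else:
            scale = np.sqrt(1.0 / fan_in)
        self.w = rng.normal(0.0, scale, size=(kernel, kernel, kernel, c_in, c_out)).astype(
            np.float32
        )
        self.b = np.full(c_out, bias_init, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._xp: np.ndarray | None = None
        self._y: np.ndarray | None = None

    @property
    def params(self) -> list[np.ndarray]:
        return [self.w, self.b]

    @property
    def grads(self) -> list[np.ndarray]:
        return [self.dw, self.db]

    def _offsets(self):
        return itertools.product(range(self.kernel), repeat=3)

    def _pad(self, x: np.ndarray) -> np.ndarray:
        p = self.kernel // 2
        if not p:
            return x
        n, d, h, w, _ = x.shape
        xp = np.zeros((n, d + 2 * p, h + 2 * p, w + 2 * p, self.c_in), dtype=np.float32)
        xp[:, p : p + d, p : p + h, p : p + w] = x
        return xp

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, d, h, w, _ = x.shape
        xp = self._pad(x)
        y2 = np.tile(self.b, (n * d * h * w, 1)).astype(np.float32)
        for dz, dy, dx in self._offsets():
            patch = xp[:, dz : dz + d, dy : dy + h, dx : dx + w, :]
            y2 += patch.reshape(-1, self.c_in) @ self.w[dz, dy, dx]
        if train:
            self._xp = xp
        y = y2.reshape(n, d, h, w, self.c_out)
        if self.relu:
            np.maximum(y, 0.0, out=y)
        if train:
            self._y = y
        return y

    def backward(self, grad: np.ndarray, need_input_grad: bool = True) -> np.ndarray | None:
        assert self._y is not None, "backward() requires forward(train=True)"
        k = self.kernel
        p = k // 2
        n, d, h, w, _ = grad.shape
        if self.relu:
            grad = grad * (self._y > 0)
        g2 = np.ascontiguousarray(grad.reshape(-1, self.c_out))
        self.db[...] = g2.sum(axis=0)
        gxp = np.zeros_like(self._xp) if need_input_grad else None
        for dz, dy, dx in self._offsets():
            patch = self._xp[:, dz : dz + d, dy : dy + h, dx : dx + w, :]
            p2 = patch.reshape(-1, self.c_in)
            self.dw[dz, dy, dx] = p2.T @ g2
            if need_input_grad:
                gxp[:, dz : dz + d, dy : dy + h, dx : dx + w, :] += (
                    g2 @ self.w[dz, dy, dx].T
                ).reshape(n, d, h, w, self.c_in)
        self._xp = self._y = None
        if not need_input_grad:
            return None
        if p:
            return gxp[:, p : p + d, p : p + h, p : p + w, :]
        return gxp


class MaxPool3d(Layer):
    """Non-overlapping max pooling with a cubic patch; requires divisibility."""

    def __init__(self, size: int):
        self.size = size
        self._x = None
        self._y = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        s = self.size
        n, d, h, w, c = x.shape
        if d % s or h % s or w % s:
            raise ValueError(f"spatial dims {(d, h, w)} not divisible by pool size {s}")
        xr = x.reshape(n, d // s, s, h // s, s, w // s, s, c)
        y = xr.max(axis=(2, 4, 6))
        if train:
            self._x, self._y = x, y
        return y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        s = self.size
        x, y = self._x, self._y
        self._x = self._y = None
        up = np.repeat(np.repeat(np.repeat(y, s, axis=1), s, axis=2), s, axis=3)
        gup = np.repeat(np.repeat(np.repeat(grad, s, axis=1), s, axis=2), s, axis=3)
        mask = x == up
        # ties (frequent after ReLU) share the gradient equally, so the
        # pooled gradient is conserved and matches finite differences
        n, d, h, w, c = x.shape
        counts = mask.reshape(n, d // s, s, h // s, s, w // s, s, c).sum(axis=(2, 4, 6))
        cup = np.repeat(np.repeat(np.repeat(counts, s, axis=1), s, axis=2), s, axis=3)
        return np.where(mask, gup / cup, 0.0).astype(np.float32)


class Upsample3d(Layer):
    """Parameter-free nearest-neighbor up-sampling (repeat each voxel s times)."""

    def __init__(self, size: int):
        self.size = size

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        s = self.size
        return np.repeat(np.repeat(np.repeat(x, s, axis=1), s, axis=2), s, axis=3)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        s = self.size
        n, d, h, w, c = grad.shape
        gr = grad.reshape(n, d // s, s, h // s, s, w // s, s, c)
        return np.ascontiguousarray(gr.sum(axis=(2, 4, 6)), dtype=np.float32)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out
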