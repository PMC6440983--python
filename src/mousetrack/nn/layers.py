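"""Layers with explicit forward/backward passes.

Convolution is im2col + GEMM; transposed convolution is the exact adjoint
(scatter over kernel offsets), so `ConvTranspose2d` composed with `Conv2d`
gradient-checks against finite differences.  Shapes are asserted eagerly:
a mis-specified architecture fails at build/probe time, not mid-training.
"""

from __future__ import annotations

from typing import List, Optional

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Parameter:
    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)
        self.name = name

    @property
    def shape(self):
        return self.value.shape


class Layer:
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> List[Parameter]:
        return []

    def __call__(self, x, training: bool = False):
        return self.forward(x, training)


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class Conv2d(Layer):
    """2-D convolution, stride 1, 'same' zero padding (pad = k // 2)."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 name: str = "conv"):
        self.c_in, self.c_out, self.k = c_in, c_out, k
        self.pad = k // 2
        fan_in = c_in * k * k
        self.w = Parameter(_he_init(rng, (c_out, fan_in), fan_in), f"{name}.w")
        self.b = Parameter(np.zeros(c_out, dtype=np.float32), f"{name}.b")
        self._cols: Optional[np.ndarray] = None
        self._xshape = None

    def forward(self, x, training=False):
        n, c, h, w = x.shape
        assert c == self.c_in, f"expected {self.c_in} channels, got {c}"
        p, k = self.pad, self.k
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(xp, (k, k), axis=(2, 3))     # n,c,h,w,k,k
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)
                                    ).reshape(n * h * w, c * k * k)
        out = cols @ self.w.value.T + self.b.value
        self._cols = cols if training else None
        self._xshape = (n, c, h, w)
        return np.ascontiguousarray(
            out.reshape(n, h, w, self.c_out).transpose(0, 3, 1, 2))

    def backward(self, grad):
        n, c, h, w = self._xshape
        p, k = self.pad, self.k
        g = np.ascontiguousarray(grad.transpose(0, 2, 3, 1)
                                 ).reshape(n * h * w, self.c_out)
        self.w.grad += g.T @ self._cols
        self.b.grad += g.sum(axis=0)
        dcols = (g @ self.w.value).reshape(n, h, w, c, k, k)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=np.float32)
        for ki in range(k):
            for kj in range(k):
                dxp[:, :, ki:ki + h, kj:kj + w] += dcols[:, :, :, :, ki, kj
                                                         ].transpose(0, 3, 1, 2)
        self._cols = None
        return dxp[:, :, p:p + h, p:p + w]

    def params(self):
        return [self.w, self.b]


class ConvTranspose2d(Layer):
    """Strided transposed convolution (the adjoint of a strided conv).

    out_size = (in - 1) * stride - 2 * padding + k + output_padding
    """

    def __init__(self, c_in: int, c_out: int, k: int, stride: int,
                 padding: int, output_padding: int, rng: np.random.Generator,
                 name: str = "convT"):
        self.c_in, self.c_out, self.k = c_in, c_out, k
        self.s, self.p, self.op = stride, padding, output_padding
        if not 0 <= output_padding < stride:
            raise ValueError("output_padding must be in [0, stride)")
        fan_in = c_in * k * k // (stride * stride)  # effective inputs per output
        self.w = Parameter(
            rng.normal(0.0, np.sqrt(1.0 / max(fan_in, 1)),
                       size=(c_in, c_out, k, k)).astype(np.float32),
            f"{name}.w")
        self.b = Parameter(np.zeros(c_out, dtype=np.float32), f"{name}.b")
        self._x = None

    def out_size(self, n: int) -> int:
        return (n - 1) * self.s - 2 * self.p + self.k + self.op

    def forward(self, x, training=False):
        n, c, h, w = x.shape
        assert c == self.c_in
        s, p, k = self.s, self.p, self.k
        ho, wo = self.out_size(h), self.out_size(w)
        fh, fw = (h - 1) * s + k + self.op, (w - 1) * s + k + self.op
        t = np.tensordot(x, self.w.value, axes=([1], [0]))  # n,h,w,co,k,k
        full = np.zeros((n, self.c_out, fh, fw), dtype=np.float32)
        for ki in range(k):
            for kj in range(k):
                full[:, :, ki:ki + (h - 1) * s + 1:s,
                     kj:kj + (w - 1) * s + 1:s] += t[:, :, :, :, ki, kj
                                                     ].transpose(0, 3, 1, 2)
        out = full[:, :, p:p + ho, p:p + wo] + self.b.value[None, :, None, None]
        self._x = x if training else None
        self._xshape = (n, c, h, w)
        return out

    def backward(self, grad):
        n, c, h, w = self._xshape
        s, p, k = self.s, self.p, self.k
        ho, wo = self.out_size(h), self.out_size(w)
        fh, fw = (h - 1) * s + k + self.op, (w - 1) * s + k + self.op
        gfull = np.zeros((n, self.c_out, fh, fw), dtype=np.float32)
        gfull[:, :, p:p + ho, p:p + wo] = grad
        self.b.grad += grad.sum(axis=(0, 2, 3))
        dt = np.empty((n, h, w, self.c_out, k, k), dtype=np.float32)
        for ki in range(k):
            for kj in range(k):
                dt[:, :, :, :, ki, kj] = gfull[
                    :, :, ki:ki + (h - 1) * s + 1:s,
                    kj:kj + (w - 1) * s + 1:s].transpose(0, 2, 3, 1)
        self.w.grad += np.tensordot(self._x, dt, axes=([0, 2, 3], [0, 1, 2]))
        dx = np.tensordot(dt, self.w.value, axes=([3, 4, 5], [1, 2, 3]))
        self._x = None
        return np.ascontiguousarray(dx.transpose(0, 3, 1, 2))

    def params(self):
        return [self.w, self.b]


class MaxPool2d(Layer):
    """Non-overlapping max pooling (kernel == stride); input must divide."""

    def __init__(self, k: int):
        self.k = k
        self._idx = None

    def forward(self, x, training=False):
        n, c, h, w = x.shape
        k = self.k
        assert h % k == 0 and w % k == 0, f"{h}x{w} not divisible by pool {k}"
        ho, wo = h // k, w // k
        xr = x.reshape(n, c, ho, k, wo, k).transpose(0, 1, 2, 4, 3, 5
                                                     ).reshape(n, c, ho, wo, k * k)
        idx = xr.argmax(axis=-1)
        out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        self._idx = idx if training else None
        self._xshape = (n, c, h, w)
        return out

    def backward(self, grad):
        n, c, h, w = self._xshape
        k = self.k
        ho, wo = h // k, w // k
        dxr = np.zeros((n, c, ho, wo, k * k), dtype=np.float32)
        np.put_along_axis(dxr, self._idx[..., None], grad[..., None], axis=-1)
        self._idx = None
        return dxr.reshape(n, c, ho, wo, k, k).transpose(0, 1, 2, 4, 3, 5
                                                         ).reshape(n, c, h, w)


class BatchNorm2d(Layer):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5,
                 name: str = "bn"):
        self.c, self.momentum, self.eps = c, momentum, eps
        self.gamma = Parameter(np.ones(c, dtype=np.float32), f"{name}.gamma")
        self.beta = Parameter(np.zeros(c, dtype=np.float32), f"{name}.beta")
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self._cache = None

    def forward(self, x, training=False):
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(np.float32)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        out = (self.gamma.value[None, :, None, None] * xhat
               + self.beta.value[None, :, None, None])
        self._cache = (xhat, inv) if training else None
        return out.astype(np.float32)

    def backward(self, grad):
        xhat, inv = self._cache
        m = grad.shape[0] * grad.shape[2] * grad.shape[3]
        self.gamma.grad += (grad * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += grad.sum(axis=(0, 2, 3))
        g = self.gamma.value[None, :, None, None]
        sum_g = grad.sum(axis=(0, 2, 3)).reshape(1, -1, 1, 1)
        sum_gx = (grad * xhat).sum(axis=(0, 2, 3)).reshape(1, -1, 1, 1)
        dx = (g * inv[None, :, None, None] / m
              * (m * grad - sum_g - xhat * sum_gx))
        self._cache = None
        return dx.astype(np.float32)

    def params(self):
        return [self.gamma, self.beta]

    def buffers(self):
        return {"running_mean": self.running_mean, "running_var": self.running_var}


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0 if training else None
        return np.maximum(x, 0.0)

    def backward(self, grad):
        out = grad * self._mask
        self._mask = None
        return out


class Flatten(Layer):
    def forward(self, x, training=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 name: str = "fc"):
        self.w = Parameter(
            rng.normal(0.0, np.sqrt(1.0 / n_in), size=(n_out, n_in)
                       ).astype(np.float32), f"{name}.w")
        self.b = Parameter(np.zeros(n_out, dtype=np.float32), f"{name}.b")
        self._x = None

    def forward(self, x, training=False):
        self._x = x if training else None
        return x @ self.w.value.T + self.b.value

    def backward(self, grad):
        self.w.grad += grad.T @ self._x
        self.b.grad += grad.sum(axis=0)
        dx = grad @ self.w.value
        self._x = None
        return dx

    def params(self):
        return [self.w, self.b]


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self):
        return [p for layer in self.layers for p in layer.params()]
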