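"""Minimal NumPy neural-network core: layers, backprop, SGD.

Implements exactly the layer vocabulary the MIL networks need — same-padded
2-D convolution, non-overlapping max-pooling, global average pooling, dense
layers with fused activations, and inverted dropout — with hand-written
backward passes.  Convolutions are evaluated as a single im2col matrix
product per layer so that all heavy lifting lands in BLAS.

Layout is NHWC throughout; instances of a bag travel through the shared
encoder as the batch dimension.  Parameters default to float32 for speed;
pass ``dtype=np.float64`` when building a network for finite-difference
gradient checking.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param",
    "Layer",
    "Conv2D",
    "MaxPool2D",
    "GlobalAvgPool",
    "Dense",
    "Dropout",
    "Sequential",
    "glorot_uniform",
    "sgd_step",
]


class Param:
    """A trainable array together with its gradient accumulator."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = value
        self.grad = np.zeros_like(value)
        self.name = name

    @property
    def size(self) -> int:
        return self.value.size


def glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int, dtype):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


def _activate(z: np.ndarray, activation: str) -> np.ndarray:
    if activation == "relu":
        return np.maximum(z, 0.0)
    if activation == "tanh":
        return np.tanh(z)
    if activation == "sigmoid":
        # numerically safe logistic
        out = np.empty_like(z)
        pos = z >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
        ez = np.exp(z[~pos])
        out[~pos] = ez / (1.0 + ez)
        return out
    if activation == "none":
        return z
    raise ValueError(f"unknown activation {activation!r}")


def _activation_grad(dout: np.ndarray, out: np.ndarray, activation: str) -> np.ndarray:
    if activation == "relu":
        return dout * (out > 0)
    if activation == "tanh":
        return dout * (1.0 - out * out)
    if activation == "sigmoid":
        return dout * out * (1.0 - out)
    if activation == "none":
        return dout
    raise ValueError(f"unknown activation {activation!r}")


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x, train=False, rng=None):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout, input_grad=True):  # pragma: no cover - interface
        raise NotImplementedError


class Conv2D(Layer):
    """Same-padded stride-1 convolution with bias and fused activation.

    Weights are stored im2col-flat as ``(k*k*C_in, C_out)`` with the window
    flattened in ``(C_in, kh, kw)`` order to match
    :func:`numpy.lib.stride_tricks.sliding_window_view`.  The im2col matrix
    is materialised a few images at a time so the column buffer stays
    cache-resident instead of round-tripping through DRAM; the backward
    pass re-materialises it chunk by chunk from the cached padded input.
    """

    # target size of the chunked im2col buffer, in scalars (~8 MB float32)
    _CHUNK_ELEMS = 2_000_000

    def __init__(self, in_ch: int, out_ch: int, kernel: int, activation: str,
                 rng: np.random.Generator, dtype=np.float32):
        self.in_ch, self.out_ch, self.kernel = in_ch, out_ch, kernel
        self.activation = activation
        fan_in = kernel * kernel * in_ch
        self.W = Param(glorot_uniform(rng, (fan_in, out_ch), fan_in, out_ch, dtype), "conv.W")
        self.b = Param(np.zeros(out_ch, dtype=dtype), "conv.b")

    def params(self):
        return [self.W, self.b]

    def _chunk_images(self, h, w, c):
        per_image = h * w * c * self.kernel ** 2
        return max(1, self._CHUNK_ELEMS // per_image)

    def forward(self, x, train=False, rng=None):
        n, h, w, c = x.shape
        k, pad = self.kernel, self.kernel // 2
        xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
        windows = sliding_window_view(xp, (k, k), axis=(1, 2))  # (n,h,w,c,k,k) view
        ckk = c * k * k
        step = self._chunk_images(h, w, c)
        out = np.empty((n, h, w, self.out_ch), dtype=x.dtype)
        buf = np.empty((step * h * w, ckk), dtype=x.dtype)
        for s in range(0, n, step):
            e = min(s + step, n)
            m = (e - s) * h * w
            np.copyto(buf[:m].reshape((e - s, h, w, c, k, k)), windows[s:e])
            z = buf[:m] @ self.W.value
            z += self.b.value
            out[s:e] = _activate(z, self.activation).reshape(e - s, h, w, self.out_ch)
        self._cache = (xp, out)
        return out

    def backward(self, dout, input_grad=True):
        xp, out = self._cache
        n, h, w, _ = out.shape
        c = self.in_ch
        k, pad = self.kernel, self.kernel // 2
        dz = _activation_grad(dout, out, self.activation).reshape(n * h * w, self.out_ch)
        windows = sliding_window_view(xp, (k, k), axis=(1, 2))
        ckk = c * k * k
        step = self._chunk_images(h, w, c)
        buf = np.empty((step * h * w, ckk), dtype=dout.dtype)
        dW = np.zeros_like(self.W.value)
        dxp = np.zeros_like(xp) if input_grad else None
        for s in range(0, n, step):
            e = min(s + step, n)
            m = (e - s) * h * w
            np.copyto(buf[:m].reshape((e - s, h, w, c, k, k)), windows[s:e])
            dzc = dz[s * h * w:e * h * w]
            dW += buf[:m].T @ dzc
            if input_grad:
                dcols = (dzc @ self.W.value.T).reshape(e - s, h, w, c, k, k)
                for i in range(k):
                    for j in range(k):
                        dxp[s:e, i:i + h, j:j + w, :] += dcols[:, :, :, :, i, j]
        self.W.grad += dW
        self.b.grad += dz.sum(axis=0)
        self._cache = None
        if not input_grad:
            return None
        return dxp[:, pad:pad + h, pad:pad + w, :]


class MaxPool2D(Layer):
    """Non-overlapping max pooling (stride = window, floor division).

    Backward routes the gradient through every entry equal to the window
    maximum; exact ties therefore share the gradient.  Ties only arise in
    practice on post-ReLU zero plateaus, where the preceding activation
    gradient kills the contribution anyway.
    """

    def __init__(self, window: int):
        self.window = window

    def forward(self, x, train=False, rng=None):
        n, h, w, c = x.shape
        k = self.window
        oh, ow = h // k, w // k
        xr = x[:, :oh * k, :ow * k, :].reshape(n, oh, k, ow, k, c)
        out = xr.max(axis=(2, 4))
        self._cache = (xr, out, (n, h, w, c))
        return out

    def backward(self, dout, input_grad=True):
        xr, out, (n, h, w, c) = self._cache
        k = self.window
        oh, ow = h // k, w // k
        mask = xr == out[:, :, None, :, None, :]
        dxr = mask * dout[:, :, None, :, None, :].astype(dout.dtype)
        if h == oh * k and w == ow * k:
            self._cache = None
            return dxr.reshape(n, h, w, c)
        dx = np.zeros((n, h, w, c), dtype=dout.dtype)
        dx[:, :oh * k, :ow * k, :] = dxr.reshape(n, oh * k, ow * k, c)
        self._cache = None
        return dx


class GlobalAvgPool(Layer):
    """Mean over the two spatial axes; output (N, C) for any spatial size."""

    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dout, input_grad=True):
        n, h, w, c = self._shape
        return np.broadcast_to(dout[:, None, None, :] / (h * w), (n, h, w, c)).astype(dout.dtype)


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int, activation: str,
                 rng: np.random.Generator, dtype=np.float32):
        self.activation = activation
        self.W = Param(glorot_uniform(rng, (in_dim, out_dim), in_dim, out_dim, dtype), "dense.W")
        self.b = Param(np.zeros(out_dim, dtype=dtype), "dense.b")

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=False, rng=None):
        z = x @ self.W.value + self.b.value
        out = _activate(z, self.activation)
        self._cache = (x, out)
        return out

    def backward(self, dout, input_grad=True):
        x, out = self._cache
        dz = _activation_grad(dout, out, self.activation)
        self.W.grad += x.T @ dz
        self.b.grad += dz.sum(axis=0)
        self._cache = None
        return dz @ self.W.value.T if input_grad else None


class Dropout(Layer):
    """Inverted dropout: scales by 1/(1-rate) at train time, identity at eval."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate

    def forward(self, x, train=False, rng=None):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("Dropout in train mode needs an rng")
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        self._mask = self._mask.astype(x.dtype)
        return x * self._mask

    def backward(self, dout, input_grad=True):
        return dout if self._mask is None else dout * self._mask


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def forward(self, x, train=False, rng=None):
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=rng)
        return x

    def backward(self, dout, input_grad=True):
        for i, layer in enumerate(reversed(self.layers)):
            last = i == len(self.layers) - 1
            dout = layer.backward(dout, input_grad=input_grad or not last)
        return dout


def sgd_step(params: list[Param], lr: float, momentum: float = 0.0,
             weight_decay: float = 0.0, velocities=None):
    """Plain SGD update in place; returns the velocity buffers when momentum > 0."""
    if momentum > 0.0 and velocities is None:
        velocities = [np.zeros_like(p.value) for p in params]
    for i, p in enumerate(params):
        g = p.grad
        if weight_decay > 0.0:
            g = g + weight_decay * p.value
        if momentum > 0.0:
            velocities[i] = momentum * velocities[i] + g
            g = velocities[i]
        p.value -= lr * g
    return velocities
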