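"""Minimal deterministic neural-network core.

Purpose-built backprop engine for the gradient-reversal (GRL) networks: a
handful of layer types (dense, strided 1-D/2-D convolution, ReLU, global
average pooling), softmax/MSE losses and Adam. Everything is plain numpy,
single-threaded and bit-reproducible given seeds, which the equivalence
guarantees of the training protocol (lambda=0 == standard training) rely on.

Layers are functional: ``forward`` returns ``(y, cache)`` and ``backward``
consumes the cache, accumulates parameter gradients in-place and returns the
input gradient, so one layer instance can serve several forward passes per
step (the two-component minibatch needs exactly that from the shared
feature extractor).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Dense",
    "ReLU",
    "Conv1D",
    "Conv2D",
    "GlobalAvgPool1D",
    "GlobalAvgPool2D",
    "Flatten",
    "GradientReversal",
    "Sequential",
    "Adam",
    "softmax",
    "softmax_cross_entropy",
    "mse_loss",
]


class Param:
    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = value
        self.grad = np.zeros_like(value)
        self.name = name

    @property
    def size(self) -> int:
        return self.value.size


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x, train: bool = False):
        raise NotImplementedError

    def backward(self, cache, dy):
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, dtype=np.float32):
        scale = np.sqrt(2.0 / n_in)
        self.W = Param(rng.normal(0, scale, (n_in, n_out)).astype(dtype), "W")
        self.b = Param(np.zeros(n_out, dtype=dtype), "b")

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=False):
        return x @ self.W.value + self.b.value, x

    def backward(self, cache, dy):
        x = cache
        self.W.grad += x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.W.value.T


class ReLU(Layer):
    def forward(self, x, train=False):
        mask = x > 0
        return x * mask, mask

    def backward(self, cache, dy):
        return dy * cache


class Conv1D(Layer):
    """Valid-padding strided 1-D convolution over (B, C, L) inputs."""

    def __init__(self, c_in, c_out, k, stride, rng, dtype=np.float32):
        self.c_in, self.c_out, self.k, self.stride = c_in, c_out, k, stride
        scale = np.sqrt(2.0 / (c_in * k))
        self.W = Param(rng.normal(0, scale, (c_in * k, c_out)).astype(dtype), "W")
        self.b = Param(np.zeros(c_out, dtype=dtype), "b")

    def params(self):
        return [self.W, self.b]

    def _cols(self, x):
        B, C, L = x.shape
        Lout = (L - self.k) // self.stride + 1
        win = np.lib.stride_tricks.sliding_window_view(x, self.k, axis=2)
        cols = win[:, :, :: self.stride, :][:, :, :Lout]  # (B, C, Lout, k)
        return np.ascontiguousarray(cols.transpose(0, 2, 1, 3)).reshape(
            B, Lout, C * self.k
        )

    def forward(self, x, train=False):
        cols = self._cols(x)
        y = cols @ self.W.value + self.b.value  # (B, Lout, c_out)
        return y.transpose(0, 2, 1), (cols, x.shape)

    def backward(self, cache, dy):
        cols, xshape = cache
        B, C, L = xshape
        dy = dy.transpose(0, 2, 1)  # (B, Lout, c_out)
        Lout = dy.shape[1]
        self.W.grad += cols.reshape(-1, C * self.k).T @ dy.reshape(-1, self.c_out)
        self.b.grad += dy.sum(axis=(0, 1))
        dcols = (dy @ self.W.value.T).reshape(B, Lout, C, self.k)
        dx = np.zeros(xshape, dtype=dy.dtype)
        for t in range(self.k):
            dx[:, :, t : t + self.stride * Lout : self.stride] += dcols[
                :, :, :, t
            ].transpose(0, 2, 1)
        return dx


class Conv2D(Layer):
    """Valid-padding strided 2-D convolution over (B, C, H, W) inputs."""

    def __init__(self, c_in, c_out, k, stride, rng, dtype=np.float32):
        self.c_in, self.c_out, self.k, self.stride = c_in, c_out, k, stride
        scale = np.sqrt(2.0 / (c_in * k * k))
        self.W = Param(
            rng.normal(0, scale, (c_in * k * k, c_out)).astype(dtype), "W"
        )
        self.b = Param(np.zeros(c_out, dtype=dtype), "b")

    def params(self):
        return [self.W, self.b]

    def _cols(self, x):
        B, C, H, Wd = x.shape
        k, s = self.k, self.stride
        Ho = (H - k) // s + 1
        Wo = (Wd - k) // s + 1
        win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
        cols = win[:, :, ::s, ::s][:, :, :Ho, :Wo]  # (B, C, Ho, Wo, k, k)
        cols = np.ascontiguousarray(cols.transpose(0, 2, 3, 1, 4, 5))
        return cols.reshape(B, Ho * Wo, C * k * k), (Ho, Wo)

    def forward(self, x, train=False):
        cols, (Ho, Wo) = self._cols(x)
        y = cols @ self.W.value + self.b.value  # (B, Ho*Wo, c_out)
        B = x.shape[0]
        y = y.transpose(0, 2, 1).reshape(B, self.c_out, Ho, Wo)
        return y, (cols, x.shape, Ho, Wo)

    def backward(self, cache, dy):
        cols, xshape, Ho, Wo = cache
        B, C, H, Wd = xshape
        k, s = self.k, self.stride
        dy = dy.reshape(B, self.c_out, Ho * Wo).transpose(0, 2, 1)  # (B,HoWo,cout)
        self.W.grad += cols.reshape(-1, C * k * k).T @ dy.reshape(-1, self.c_out)
        self.b.grad += dy.sum(axis=(0, 1))
        dcols = (dy @ self.W.value.T).reshape(B, Ho, Wo, C, k, k)
        dx = np.zeros(xshape, dtype=dy.dtype)
        for i in range(k):
            for j in range(k):
                dx[:, :, i : i + s * Ho : s, j : j + s * Wo : s] += dcols[
                    :, :, :, :, i, j
                ].transpose(0, 3, 1, 2)
        return dx


class GlobalAvgPool1D(Layer):
    def forward(self, x, train=False):
        return x.mean(axis=2), x.shape

    def backward(self, cache, dy):
        B, C, L = cache
        return np.repeat(dy[:, :, None], L, axis=2) / L


class GlobalAvgPool2D(Layer):
    def forward(self, x, train=False):
        return x.mean(axis=(2, 3)), x.shape

    def backward(self, cache, dy):
        B, C, H, W = cache
        return np.broadcast_to(dy[:, :, None, None], cache).copy() / (H * W)


class Flatten(Layer):
    def forward(self, x, train=False):
        return x.reshape(x.shape[0], -1), x.shape

    def backward(self, cache, dy):
        return dy.reshape(cache)


class GradientReversal(Layer):
    """Identity in the forward pass; multiplies gradients by -lambda backward."""

    def __init__(self, lam: float = 1.0):
        if lam < 0:
            raise ValueError("lambda must be non-negative")
        self.lam = float(lam)

    def forward(self, x, train=False):
        return x, None

    def backward(self, cache, dy):
        return -self.lam * dy


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = list(layers)

    def params(self):
        out = []
        for l in self.layers:
            out.extend(l.params())
        return out

    def forward(self, x, train=False):
        caches = []
        for l in self.layers:
            x, c = l.forward(x, train=train)
            caches.append(c)
        return x, caches

    def backward(self, caches, dy):
        for l, c in zip(reversed(self.layers), reversed(caches)):
            dy = l.backward(c, dy)
        return dy

    def n_params(self) -> int:
        return sum(p.size for p in self.params())


def softmax(z):
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits, labels):
    """Mean cross-entropy over the batch; returns (loss, dlogits)."""
    p = softmax(logits)
    B = logits.shape[0]
    eps = np.finfo(p.dtype).tiny
    loss = -np.log(p[np.arange(B), labels] + eps).mean()
    d = p.copy()
    d[np.arange(B), labels] -= 1.0
    return float(loss), d / B


def mse_loss(pred, y):
    """Mean squared error; returns (loss, dpred)."""
    pred = pred.reshape(-1)
    r = pred - y
    B = pred.shape[0]
    return float((r**2).mean()), (2.0 * r / B).reshape(-1, 1)


class Adam:
    def __init__(self, params: list[Param], lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0

    def step(self):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
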