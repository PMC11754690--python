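"""A compact convolutional-network engine on numpy.

Implements exactly the pieces the multi-head hologram classifier needs:
standard and depth-wise 2-D convolutions (im2col, with hand-derived
backward passes), ReLU6, average pooling, dense layers, inverted-residual
bottleneck blocks (1x1 expansion with ReLU6, depth-wise 3x3 with ReLU6,
linear 1x1 projection, shortcut only at stride 1), softmax cross-entropy,
and Adam.  Everything is float32 and deterministic given the initialization
generator and batch order, so training histories are exactly reproducible.

Layers follow a minimal protocol: ``forward(x)`` caches what ``backward``
needs; ``backward(grad)`` accumulates parameter gradients and returns the
input gradient.  Arrays are NCHW.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Parameter",
    "Layer",
    "Conv2d",
    "DepthwiseConv2d",
    "Dense",
    "ReLU6",
    "AvgPool2d",
    "GlobalAvgPool",
    "Flatten",
    "Sequential",
    "InvertedResidual",
    "softmax",
    "softmax_cross_entropy",
    "Adam",
]

DTYPE = np.float32


class Parameter:
    """A trainable array with its gradient accumulator."""

    def __init__(self, value: np.ndarray) -> None:
        self.value = np.asarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0

    @property
    def size(self) -> int:
        return self.value.size


class Layer:
    def parameters(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


def _windows(x: np.ndarray, k: int, stride: int) -> np.ndarray:
    """Sliding kxk windows of an NCHW array -> (N, C, Ho, Wo, k, k)."""
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    return win[:, :, ::stride, ::stride]


class Conv2d(Layer):
    """kxk convolution via im2col.  ``pad`` zeros on each border."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int = 3,
        stride: int = 1,
        pad: int | None = None,
        rng: np.random.Generator | None = None,
    ) -> None:
        if stride not in (1, 2):
            raise ValueError("stride must be 1 or 2")
        rng = rng or np.random.default_rng()
        self.cin, self.cout, self.k, self.stride = in_channels, out_channels, kernel_size, stride
        self.pad = (kernel_size - 1) // 2 if pad is None else pad
        fan_in = in_channels * kernel_size * kernel_size
        self.weight = Parameter(rng.normal(0.0, np.sqrt(2.0 / fan_in), (fan_in, out_channels)))
        self.bias = Parameter(np.zeros(out_channels))

    def parameters(self) -> list[Parameter]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.pad:
            x = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad), (self.pad, self.pad)))
        self._xshape = x.shape
        n = x.shape[0]
        win = _windows(x, self.k, self.stride)  # (N,C,Ho,Wo,k,k)
        ho, wo = win.shape[2], win.shape[3]
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, -1)
        self._cols, self._ho, self._wo = cols, ho, wo
        out = cols @ self.weight.value + self.bias.value
        return out.reshape(n, ho, wo, self.cout).transpose(0, 3, 1, 2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n = grad.shape[0]
        ho, wo = self._ho, self._wo
        gmat = grad.transpose(0, 2, 3, 1).reshape(n * ho * wo, self.cout)
        self.weight.grad += self._cols.T @ gmat
        self.bias.grad += gmat.sum(axis=0)
        dcols = (gmat @ self.weight.value.T).reshape(n, ho, wo, self.cin, self.k, self.k)
        dcols = dcols.transpose(0, 3, 4, 5, 1, 2)  # (N,C,k,k,Ho,Wo)
        dx = np.zeros(self._xshape, dtype=DTYPE)
        s = self.stride
        for i in range(self.k):
            for j in range(self.k):
                dx[:, :, i : i + s * ho : s, j : j + s * wo : s] += dcols[:, :, i, j]
        if self.pad:
            dx = dx[:, :, self.pad : -self.pad, self.pad : -self.pad]
        return dx


class DepthwiseConv2d(Layer):
    """Per-channel (depth-wise) kxk spatial convolution."""

    def __init__(
        self,
        channels: int,
        kernel_size: int = 3,
        stride: int = 1,
        rng: np.random.Generator | None = None,
    ) -> None:
        if stride not in (1, 2):
            raise ValueError("stride must be 1 or 2")
        rng = rng or np.random.default_rng()
        self.c, self.k, self.stride = channels, kernel_size, stride
        self.pad = (kernel_size - 1) // 2
        fan_in = kernel_size * kernel_size
        self.weight = Parameter(
            rng.normal(0.0, np.sqrt(2.0 / fan_in), (channels, kernel_size, kernel_size))
        )
        self.bias = Parameter(np.zeros(channels))

    def parameters(self) -> list[Parameter]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.pad:
            x = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad), (self.pad, self.pad)))
        self._xshape = x.shape
        win = _windows(x, self.k, self.stride)  # (N,C,Ho,Wo,k,k)
        self._win = win
        out = np.einsum("nchwij,cij->nchw", win, self.weight.value, optimize=True)
        return out + self.bias.value[None, :, None, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.weight.grad += np.einsum("nchw,nchwij->cij", grad, self._win, optimize=True)
        self.bias.grad += grad.sum(axis=(0, 2, 3))
        ho, wo = grad.shape[2], grad.shape[3]
        dx = np.zeros(self._xshape, dtype=DTYPE)
        s = self.stride
        for i in range(self.k):
            for j in range(self.k):
                dx[:, :, i : i + s * ho : s, j : j + s * wo : s] += (
                    grad * self.weight.value[None, :, i, j, None, None]
                )
        if self.pad:
            dx = dx[:, :, self.pad : -self.pad, self.pad : -self.pad]
        return dx


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator | None = None) -> None:
        rng = rng or np.random.default_rng()
        self.weight = Parameter(rng.normal(0.0, np.sqrt(2.0 / n_in), (n_in, n_out)))
        self.bias = Parameter(np.zeros(n_out))

    def parameters(self) -> list[Parameter]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.weight.value + self.bias.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.weight.grad += self._x.T @ grad
        self.bias.grad += grad.sum(axis=0)
        return grad @ self.weight.value.T


class ReLU6(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = (x > 0) & (x < 6)
        return np.clip(x, 0.0, 6.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class AvgPool2d(Layer):
    """Non-overlapping f x f average pooling (fixed, no parameters)."""

    def __init__(self, factor: int) -> None:
        self.f = factor

    def forward(self, x: np.ndarray) -> np.ndarray:
        f = self.f
        n, c, h, w = x.shape
        hc, wc = (h // f) * f, (w // f) * f
        self._in_shape = x.shape
        xv = x[:, :, :hc, :wc].reshape(n, c, hc // f, f, wc // f, f)
        return xv.mean(axis=(3, 5))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        f = self.f
        dx = np.zeros(self._in_shape, dtype=DTYPE)
        up = np.repeat(np.repeat(grad, f, axis=2), f, axis=3) / (f * f)
        dx[:, :, : up.shape[2], : up.shape[3]] = up
        return dx


class GlobalAvgPool(Layer):
    """Spatial mean -> (N, C)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return np.broadcast_to(grad[:, :, None, None], self._shape).astype(DTYPE) / (h * w)


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Sequential(Layer):
    def __init__(self, *layers: Layer) -> None:
        self.layers = list(layers)

    def parameters(self) -> list[Parameter]:
        return [p for layer in self.layers for p in layer.parameters()]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


class InvertedResidual(Layer):
    """MobileNetV2-style bottleneck: 1x1 expand + ReLU6, depth-wise 3x3 +
    ReLU6, linear 1x1 projection; identity shortcut only when stride is 1 and
    the channel count is preserved."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        stride: int = 1,
        expansion: int = 2,
        rng: np.random.Generator | None = None,
    ) -> None:
        rng = rng or np.random.default_rng()
        mid = in_channels * expansion
        self.body = Sequential(
            Conv2d(in_channels, mid, kernel_size=1, pad=0, rng=rng),
            ReLU6(),
            DepthwiseConv2d(mid, kernel_size=3, stride=stride, rng=rng),
            ReLU6(),
            Conv2d(mid, out_channels, kernel_size=1, pad=0, rng=rng),
        )
        self.use_shortcut = stride == 1 and in_channels == out_channels

    def parameters(self) -> list[Parameter]:
        return self.body.parameters()

    def forward(self, x: np.ndarray) -> np.ndarray:
        out = self.body.forward(x)
        return out + x if self.use_shortcut else out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        dx = self.body.backward(grad)
        return dx + grad if self.use_shortcut else dx


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Mean cross-entropy loss, its gradient w.r.t. logits, and the class
    probabilities."""
    probs = softmax(logits.astype(np.float64))
    n = logits.shape[0]
    loss = float(-np.log(probs[np.arange(n), labels] + 1e-12).mean())
    grad = probs.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, (grad / n).astype(DTYPE), probs


class Adam:
    """Adam with constant learning rate (the optimizer used for all stages)."""

    def __init__(
        self,
        params: list[Parameter],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * p.grad
            v[...] = self.b2 * v + (1 - self.b2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
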