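"""Minimal NumPy neural-network engine for 2D convolutional residual nets.

Layers operate on float32 arrays in (batch, channels, height, width) layout
and implement explicit forward/backward passes, which keeps the whole stack
free of compiled deep-learning dependencies and makes every numerical step
inspectable.  Convolutions use 'same' padding and run as im2col + BLAS
matmul, so a CPU forward pass over a 64 x 64 crop of the full-size network
stays in the seconds range.
"""

from __future__ import annotations

import numpy as np


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    training: bool = False

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _he_init(rng: np.random.Generator, shape: tuple[int, ...],
             fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Conv2d(Layer):
    """k x k convolution with 'same' zero padding and optional dilation."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 dilation: int = 1, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        self.dilation = dilation
        fan_in = in_channels * kernel * kernel
        self.weight = Param(_he_init(rng, (out_channels, fan_in), fan_in))
        self.bias = Param(np.zeros(out_channels, dtype=np.float32))
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def _pad(self) -> int:
        return self.dilation * (self.kernel - 1) // 2

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        B, C, H, W = x.shape
        k, d, p = self.kernel, self.dilation, self._pad()
        if k == 1:
            return x.reshape(B, C, H * W)
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        col = np.empty((B, C, k, k, H, W), dtype=np.float32)
        for ki in range(k):
            for kj in range(k):
                col[:, :, ki, kj] = xp[:, :, ki * d: ki * d + H,
                                       kj * d: kj * d + W]
        return col.reshape(B, C * k * k, H * W)

    def _col2im(self, gcol: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
        B, C, H, W = shape
        k, d, p = self.kernel, self.dilation, self._pad()
        if k == 1:
            return gcol.reshape(B, C, H, W)
        gcol = gcol.reshape(B, C, k, k, H, W)
        gxp = np.zeros((B, C, H + 2 * p, W + 2 * p), dtype=np.float32)
        for ki in range(k):
            for kj in range(k):
                gxp[:, :, ki * d: ki * d + H,
                    kj * d: kj * d + W] += gcol[:, :, ki, kj]
        return gxp[:, :, p: p + H, p: p + W]

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, C, H, W = x.shape
        if C != self.in_channels:
            raise ValueError(
                f"conv expected {self.in_channels} input channels, got {C}"
            )
        col = self._im2col(x)
        out = np.matmul(self.weight.value, col)
        out += self.bias.value[None, :, None]
        self._cache = (col, x.shape)
        return out.reshape(B, self.out_channels, H, W)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        col, shape = self._cache
        B, _, H, W = shape
        g = grad.reshape(B, self.out_channels, H * W)
        self.weight.grad += np.einsum("boh,bch->oc", g, col,
                                      optimize=True)
        self.bias.grad += g.sum(axis=(0, 2))
        gcol = np.matmul(self.weight.value.T, g)
        return self._col2im(gcol, shape)


class CollapseConv(Layer):
    """Full-extent convolution collapsing one spatial axis.

    With ``collapse_axis=3`` this is a (1 x W) kernel producing one output
    vector per row i; with ``collapse_axis=2`` a (H x 1) kernel producing
    one per column j.  Used by the per-residue auxiliary heads.
    """

    def __init__(self, in_channels: int, out_channels: int, extent: int,
                 collapse_axis: int, rng: np.random.Generator | None = None):
        if collapse_axis not in (2, 3):
            raise ValueError("collapse_axis must be 2 (height) or 3 (width)")
        rng = rng or np.random.default_rng(0)
        fan_in = in_channels * extent
        self.weight = Param(_he_init(rng, (out_channels, in_channels, extent),
                                     fan_in))
        self.bias = Param(np.zeros(out_channels, dtype=np.float32))
        self.extent = extent
        self.collapse_axis = collapse_axis
        self._cache: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[self.collapse_axis] != self.extent:
            raise ValueError(
                f"axis {self.collapse_axis} has size {x.shape[self.collapse_axis]}, "
                f"kernel extent is {self.extent}"
            )
        self._cache = x
        if self.collapse_axis == 3:   # out[b,o,i] over rows
            out = np.einsum("bchw,ocw->boh", x, self.weight.value, optimize=True)
        else:                          # out[b,o,j] over columns
            out = np.einsum("bchw,och->bow", x, self.weight.value, optimize=True)
        return out + self.bias.value[None, :, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x = self._cache
        if self.collapse_axis == 3:
            self.weight.grad += np.einsum("boh,bchw->ocw", grad, x, optimize=True)
            gx = np.einsum("boh,ocw->bchw", grad, self.weight.value, optimize=True)
        else:
            self.weight.grad += np.einsum("bow,bchw->och", grad, x, optimize=True)
            gx = np.einsum("bow,och->bchw", grad, self.weight.value, optimize=True)
        self.bias.grad += grad.sum(axis=(0, 2))
        return gx


class BatchNorm2d(Layer):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = Param(np.ones(channels, dtype=np.float32))
        self.beta = Param(np.zeros(channels, dtype=np.float32))
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv)
        return self.gamma.value[None, :, None, None] * xhat \
            + self.beta.value[None, :, None, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        n = grad.shape[0] * grad.shape[2] * grad.shape[3]
        self.gamma.grad += (grad * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += grad.sum(axis=(0, 2, 3))
        g = grad * self.gamma.value[None, :, None, None]
        if not self.training:
            return g * inv[None, :, None, None]
        gsum = g.sum(axis=(0, 2, 3), keepdims=True)
        gx_sum = (g * xhat).sum(axis=(0, 2, 3), keepdims=True)
        return (g - gsum / n - xhat * gx_sum / n) * inv[None, :, None, None]


class ELU(Layer):
    def __init__(self, alpha: float = 1.0):
        self.alpha = alpha
        self._cache: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        out = np.where(x > 0, x,
                       self.alpha * np.expm1(np.minimum(x, 0.0))).astype(np.float32)
        self._cache = out
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        out = self._cache
        return grad * np.where(out > 0, 1.0, out + self.alpha).astype(np.float32)


class SpatialDropout(Layer):
    """Channel-wise dropout; identity in evaluation mode."""

    def __init__(self, rate: float, rng: np.random.Generator | None = None):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng or np.random.default_rng(0)
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if not self.training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        mask = (self.rng.random((x.shape[0], x.shape[1], 1, 1)) < keep)
        self._mask = mask.astype(np.float32) / keep
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return grad
        return grad * self._mask


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self) -> list[Param]:
        return [p for l in self.layers for p in l.params()]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for l in reversed(self.layers):
            grad = l.backward(grad)
        return grad


class ResidualBlock(Layer):
    """Pre-activation bottleneck residual block.

    BN - ELU - 1x1 (to bottleneck) - BN - ELU - 3x3 dilated - dropout -
    BN - ELU - 1x1 (to out) - identity addition.  When in and out widths
    differ the skip path carries a learned 1x1 projection.
    """

    def __init__(self, in_channels: int, out_channels: int, dilation: int,
                 dropout_rate: float = 0.0,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        bottleneck = max(out_channels // 2, 1)
        self.body = Sequential(
            BatchNorm2d(in_channels), ELU(),
            Conv2d(in_channels, bottleneck, 1, rng=rng),
            BatchNorm2d(bottleneck), ELU(),
            Conv2d(bottleneck, bottleneck, 3, dilation=dilation, rng=rng),
            SpatialDropout(dropout_rate, rng=rng),
            BatchNorm2d(bottleneck), ELU(),
            Conv2d(bottleneck, out_channels, 1, rng=rng),
        )
        self.projection: Conv2d | None = None
        if in_channels != out_channels:
            self.projection = Conv2d(in_channels, out_channels, 1, rng=rng)
        self.dilation = dilation
        self.in_channels = in_channels
        self.out_channels = out_channels

    def params(self) -> list[Param]:
        ps = self.body.params()
        if self.projection is not None:
            ps += self.projection.params()
        return ps

    def forward(self, x: np.ndarray) -> np.ndarray:
        y = self.body.forward(x)
        skip = x if self.projection is None else self.projection.forward(x)
        return y + skip

    def backward(self, grad: np.ndarray) -> np.ndarray:
        gx = self.body.backward(grad)
        if self.projection is None:
            return gx + grad
        return gx + self.projection.backward(grad)


def iter_layers(layer: Layer):
    """Depth-first iteration over all layers in a tree of containers."""
    yield layer
    if isinstance(layer, Sequential):
        for sub in layer.layers:
            yield from iter_layers(sub)
    elif isinstance(layer, ResidualBlock):
        yield from iter_layers(layer.body)
        if layer.projection is not None:
            yield from iter_layers(layer.projection)


def set_training(layer: Layer, training: bool) -> None:
    for l in iter_layers(layer):
        l.training = training


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def cross_entropy(logits: np.ndarray, labels: np.ndarray,
                  ignore_value: int = -1) -> tuple[float, np.ndarray]:
    """Mean softmax cross-entropy over non-ignored positions.

    ``logits``: (N, K); ``labels``: (N,) int with ``ignore_value`` marking
    excluded positions.  Returns the scalar loss and d(loss)/d(logits);
    an all-ignored input contributes 0 loss and zero gradient.
    """
    labels = np.asarray(labels)
    valid = labels != ignore_value
    n_valid = int(valid.sum())
    grad = np.zeros_like(logits, dtype=np.float32)
    if n_valid == 0:
        return 0.0, grad
    probs = softmax(logits[valid].astype(np.float64), axis=1)
    picked = probs[np.arange(n_valid), labels[valid]]
    loss = float(-np.log(np.clip(picked, 1e-30, None)).mean())
    g = probs
    g[np.arange(n_valid), labels[valid]] -= 1.0
    grad[valid] = (g / n_valid).astype(np.float32)
    return loss, grad


class Adam:
    """Adam optimizer with the common defaults."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1.0 - self.beta1) * (p.grad - m)
            v += (1.0 - self.beta2) * (p.grad ** 2 - v)
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
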