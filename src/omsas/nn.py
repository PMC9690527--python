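"""Minimal NumPy neural-network layers with analytic backpropagation.

All layers operate on batched feature maps of shape ``(N, C, H, W)`` in
float64 (float32 optional) and cache whatever the backward pass needs.
Every gradient here is verified against central finite differences in the
test suite, so the layers can be trusted as building blocks for the
segmentation network.

Conventions
-----------
* ``forward(x)`` returns the output and caches intermediates on ``self``.
* ``backward(grad_out)`` consumes the upstream gradient, accumulates
  parameter gradients in ``Param.grad``, and returns the gradient with
  respect to the layer input.
* ``params()`` yields all trainable :class:`Param` objects (depth first).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    """A trainable tensor together with its accumulated gradient."""

    __slots__ = ("name", "value", "grad")

    def __init__(self, name: str, value: np.ndarray):
        self.name = name
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)

    @property
    def size(self) -> int:
        return self.value.size

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Module:
    """Base class: a callable layer with parameters and a backward pass."""

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def params(self):
        for attr in vars(self).values():
            if isinstance(attr, Param):
                yield attr
            elif isinstance(attr, Module):
                yield from attr.params()
            elif isinstance(attr, (list, tuple)):
                for item in attr:
                    if isinstance(item, Module):
                        yield from item.params()

    def n_params(self) -> int:
        return sum(p.size for p in self.params())

    def zero_grad(self) -> None:
        for p in self.params():
            p.zero_grad()

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


def he_uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    """He/Kaiming uniform initialisation for ReLU networks."""
    limit = np.sqrt(6.0 / max(1, fan_in))
    return rng.uniform(-limit, limit, size=shape)


class Conv1x1(Module):
    """Pointwise convolution: a linear map across channels."""

    def __init__(self, in_channels: int, out_channels: int,
                 rng: np.random.Generator, bias: bool = True):
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.weight = Param("conv1x1.weight",
                            he_uniform(rng, (out_channels, in_channels), in_channels))
        self.bias = Param("conv1x1.bias", np.zeros(out_channels)) if bias else None
        self._x = None

    def forward(self, x):
        self._x = x
        y = np.einsum("oc,nchw->nohw", self.weight.value, x, optimize=True)
        if self.bias is not None:
            y += self.bias.value[None, :, None, None]
        return y

    def backward(self, grad):
        x = self._x
        self.weight.grad += np.einsum("nohw,nchw->oc", grad, x, optimize=True)
        if self.bias is not None:
            self.bias.grad += grad.sum(axis=(0, 2, 3))
        return np.einsum("oc,nohw->nchw", self.weight.value, grad, optimize=True)


class DepthwiseConv3x3(Module):
    """3x3 convolution with one kernel per channel (padding preserves H, W)."""

    def __init__(self, channels: int, rng: np.random.Generator, bias: bool = True):
        self.channels = channels
        self.weight = Param("dwconv.weight", he_uniform(rng, (channels, 3, 3), 9))
        self.bias = Param("dwconv.bias", np.zeros(channels)) if bias else None
        self._patches = None

    @staticmethod
    def _im2col(x):
        padded = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        # (N, C, H, W, 3, 3) view over the padded array
        return sliding_window_view(padded, (3, 3), axis=(2, 3))

    def forward(self, x):
        patches = self._im2col(x)
        self._patches = patches
        y = np.einsum("nchwij,cij->nchw", patches, self.weight.value, optimize=True)
        if self.bias is not None:
            y += self.bias.value[None, :, None, None]
        return y

    def backward(self, grad):
        self.weight.grad += np.einsum("nchwij,nchw->cij", self._patches, grad,
                                      optimize=True)
        if self.bias is not None:
            self.bias.grad += grad.sum(axis=(0, 2, 3))
        # grad wrt input = correlation of grad with the 180-degree-rotated kernel
        gpatches = self._im2col(grad)
        kernel_rot = self.weight.value[:, ::-1, ::-1]
        return np.einsum("nchwij,cij->nchw", gpatches, kernel_rot, optimize=True)


class ChannelLayerNorm(Module):
    """Layer normalisation over the channel axis at each spatial position.

    Statistics are computed per (sample, row, column) across channels, with a
    learned per-channel affine transform — the standard choice for
    convolutional features when batch statistics are unreliable.
    """

    def __init__(self, channels: int, eps: float = 1e-5):
        self.channels = channels
        self.eps = eps
        self.gamma = Param("ln.gamma", np.ones(channels))
        self.beta = Param("ln.beta", np.zeros(channels))
        self._cache = None

    def forward(self, x):
        mu = x.mean(axis=1, keepdims=True)
        var = x.var(axis=1, keepdims=True)
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv_std
        self._cache = (xhat, inv_std)
        return self.gamma.value[None, :, None, None] * xhat + \
            self.beta.value[None, :, None, None]

    def backward(self, grad):
        xhat, inv_std = self._cache
        c = self.channels
        self.gamma.grad += (grad * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += grad.sum(axis=(0, 2, 3))
        gxhat = grad * self.gamma.value[None, :, None, None]
        # standard layernorm backward along the normalised axis
        term = gxhat - gxhat.mean(axis=1, keepdims=True) \
            - xhat * (gxhat * xhat).mean(axis=1, keepdims=True)
        return term * inv_std if c > 1 else np.zeros_like(grad)


class ReLU(Module):
    def __init__(self):
        self._mask = None

    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad):
        return np.where(self._mask, grad, 0.0)


class Sigmoid(Module):
    def __init__(self):
        self._y = None

    def forward(self, x):
        y = 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))
        self._y = y
        return y

    def backward(self, grad):
        y = self._y
        return grad * y * (1.0 - y)


class MaxPool2(Module):
    """2x2 max pooling with stride 2; input H, W must be even."""

    def __init__(self):
        self._cache = None

    def forward(self, x):
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"MaxPool2 needs even spatial dims, got {h}x{w}")
        blocks = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = blocks.reshape(n, c, h // 2, w // 2, 4)
        idx = flat.argmax(axis=-1)
        self._cache = (idx, x.shape)
        return np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def backward(self, grad):
        idx, (n, c, h, w) = self._cache
        buf = np.zeros((n, c, h // 2, w // 2, 4))
        np.put_along_axis(buf, idx[..., None], grad[..., None], axis=-1)
        return buf.reshape(n, c, h // 2, w // 2, 2, 2) \
                  .transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)


class UpsampleNearest2(Module):
    """Nearest-neighbour 2x upsampling."""

    def forward(self, x):
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, grad):
        n, c, h, w = grad.shape
        return grad.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


class Adam:
    """Adam optimiser over a list of :class:`Param` objects."""

    def __init__(self, params, lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in self.params]
        self._v = [np.zeros_like(p.value) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad ** 2
            p.value -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
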