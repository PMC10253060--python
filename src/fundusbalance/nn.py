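"""Minimal numpy neural-network layers, losses and optimizers.

Provides exactly what the two-stage trainer needs: 3x3 same-padding
convolutions, ReLU, 2x2 max pooling, a linear head, softmax
cross-entropy with per-class weights, and SGD / rectified-Adam
optimizers.  Convolution forward/backward are expressed as nine shifted
tensor contractions so all heavy lifting happens in BLAS.

Parameters carry a ``trainable`` flag; frozen parameters accumulate no
updates, which is how feature-extractor freezing is realized.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

__all__ = [
    "Param",
    "Conv2D",
    "ReLU",
    "MaxPool2",
    "Flatten",
    "Linear",
    "Model",
    "softmax",
    "SGD",
    "RAdam",
]


class Param:
    __slots__ = ("name", "value", "grad", "trainable")

    def __init__(self, name: str, value: np.ndarray, trainable: bool = True):
        self.name = name
        self.value = value
        self.grad = np.zeros_like(value)
        self.trainable = trainable


class Layer:
    def params(self) -> list[Param]:
        return []

    def buffers(self) -> dict[str, np.ndarray]:
        """Non-trainable state (e.g. normalization running statistics)."""
        return {}

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2D(Layer):
    """3x3 convolution, stride 1, zero same-padding, NCHW layout."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator, name: str = "conv"):
        scale = math.sqrt(2.0 / (cin * 9))
        self.w = Param(f"{name}.w", rng.normal(0, scale, (cout, cin, 3, 3)).astype(np.float32))
        self.b = Param(f"{name}.b", np.zeros(cout, dtype=np.float32))
        self._xpad: np.ndarray | None = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train=True):
        n, cin, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        self._xpad = xp if train else None
        out = np.zeros((n, h, w, self.w.value.shape[0]), dtype=x.dtype)
        W = self.w.value
        for ki in range(3):
            for kj in range(3):
                # (N,Cin,H,W) x (Cout,Cin) -> (N,H,W,Cout)
                out += np.tensordot(xp[:, :, ki : ki + h, kj : kj + w], W[:, :, ki, kj],
                                    axes=([1], [1]))
        out += self.b.value
        return np.ascontiguousarray(np.moveaxis(out, 3, 1))

    def backward(self, grad):
        xp = self._xpad
        assert xp is not None, "backward called without a training forward pass"
        n, cout, h, w = grad.shape
        W = self.w.value
        dxp = np.zeros_like(xp)
        for ki in range(3):
            for kj in range(3):
                self.w.grad[:, :, ki, kj] = np.tensordot(
                    grad, xp[:, :, ki : ki + h, kj : kj + w], axes=([0, 2, 3], [0, 2, 3])
                )
                # (N,Cout,H,W) x (Cout,Cin) -> (N,H,W,Cin)
                dslice = np.tensordot(grad, W[:, :, ki, kj], axes=([1], [0]))
                dxp[:, :, ki : ki + h, kj : kj + w] += np.moveaxis(dslice, 3, 1)
        self.b.grad[:] = grad.sum(axis=(0, 2, 3))
        return dxp[:, :, 1:-1, 1:-1]


class BatchNorm2D(Layer):
    """Per-channel batch normalization with running statistics for eval."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5,
                 name: str = "bn"):
        self.gamma = Param(f"{name}.gamma", np.ones(c, dtype=np.float32))
        self.beta = Param(f"{name}.beta", np.zeros(c, dtype=np.float32))
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def params(self):
        return [self.gamma, self.beta]

    def buffers(self):
        return {f"{self.gamma.name}.rmean": self.running_mean,
                f"{self.gamma.name}.rvar": self.running_var}

    def forward(self, x, train=True):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * invstd[None, :, None, None]
        if train:
            self._xhat, self._invstd = xhat, invstd
        g = self.gamma.value[None, :, None, None]
        return (g * xhat + self.beta.value[None, :, None, None]).astype(np.float32)

    def backward(self, grad):
        xhat, invstd = self._xhat, self._invstd
        n = grad.shape[0] * grad.shape[2] * grad.shape[3]
        self.gamma.grad[:] = (grad * xhat).sum(axis=(0, 2, 3))
        self.beta.grad[:] = grad.sum(axis=(0, 2, 3))
        dxhat = grad * self.gamma.value[None, :, None, None]
        s1 = dxhat.sum(axis=(0, 2, 3))[None, :, None, None]
        s2 = (dxhat * xhat).sum(axis=(0, 2, 3))[None, :, None, None]
        dx = (dxhat - s1 / n - xhat * s2 / n) * invstd[None, :, None, None]
        return dx.astype(np.float32)


class ReLU(Layer):
    def forward(self, x, train=True):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; input H and W must be even."""

    def forward(self, x, train=True):
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).reshape(n, c, h // 2, w // 2, 4)
        self._arg = xr.argmax(axis=4)
        self._shape = x.shape
        return np.take_along_axis(xr, self._arg[..., None], axis=4)[..., 0]

    def backward(self, grad):
        n, c, h, w = self._shape
        out = np.zeros((n, c, h // 2, w // 2, 4), dtype=grad.dtype)
        np.put_along_axis(out, self._arg[..., None], grad[..., None], axis=4)
        return out.reshape(n, c, h // 2, 2, w // 2, 2).reshape(n, c, h, w)


class Flatten(Layer):
    def forward(self, x, train=True):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Linear(Layer):
    def __init__(self, nin: int, nout: int, rng: np.random.Generator, name: str = "fc"):
        scale = math.sqrt(2.0 / nin)
        self.w = Param(f"{name}.w", rng.normal(0, scale, (nin, nout)).astype(np.float32))
        self.b = Param(f"{name}.b", np.zeros(nout, dtype=np.float32))

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train=True):
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, grad):
        self.w.grad[:] = self._x.T @ grad
        self.b.grad[:] = grad.sum(axis=0)
        return grad @ self.w.value.T


class Model:
    """Feature-extractor blocks plus a linear classification head.

    ``blocks`` is an ordered list of layer groups; the freeze rule marks
    the first ceil(fraction * n_blocks) groups non-trainable.
    """

    def __init__(self, blocks: list[list[Layer]], head: Linear,
                 head_in: int, freeze_fraction: float = 0.0):
        self.blocks = blocks
        self.head = head
        self.head_in = head_in
        self.freeze_fraction = 0.0
        self.set_freeze(freeze_fraction)

    # -- structure ---------------------------------------------------------
    def layers(self) -> list[Layer]:
        out = [layer for block in self.blocks for layer in block]
        out.append(self.head)
        return out

    def params(self) -> list[Param]:
        return [p for layer in self.layers() for p in layer.params()]

    def trainable_params(self) -> list[Param]:
        return [p for p in self.params() if p.trainable]

    def set_freeze(self, fraction: float) -> None:
        if not 0.0 <= fraction <= 1.0:
            raise ValueError("freeze fraction must be in [0, 1]")
        self.freeze_fraction = fraction
        n_frozen = math.ceil(fraction * len(self.blocks))
        for i, block in enumerate(self.blocks):
            for layer in block:
                for p in layer.params():
                    p.trainable = i >= n_frozen
        for p in self.head.params():
            p.trainable = True

    def replace_head(self, n_outputs: int, rng: np.random.Generator) -> None:
        self.head = Linear(self.head_in, n_outputs, rng, name="fc")

    @property
    def n_outputs(self) -> int:
        return self.head.w.value.shape[1]

    # -- execution ---------------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        for layer in self.layers():
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad: np.ndarray) -> None:
        for layer in reversed(self.layers()):
            grad = layer.backward(grad)

    # -- state -------------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for i, block in enumerate(self.blocks):
            for j, layer in enumerate(block):
                for p in layer.params():
                    state[f"block{i}.{j}.{p.name}"] = p.value.copy()
                for name, buf in layer.buffers().items():
                    state[f"block{i}.{j}.{name}"] = buf.copy()
        for p in self.head.params():
            state[f"head.{p.name}"] = p.value.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, block in enumerate(self.blocks):
            for j, layer in enumerate(block):
                for p in layer.params():
                    p.value[:] = state[f"block{i}.{j}.{p.name}"]
                for name, buf in layer.buffers().items():
                    buf[:] = state[f"block{i}.{j}.{name}"]
        for p in self.head.params():
            p.value[:] = state[f"head.{p.name}"]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class SGD:
    """Plain stochastic gradient descent with L2 weight decay."""

    def __init__(self, params: Sequence[Param], weight_decay: float = 0.0):
        self.params = list(params)
        self.weight_decay = weight_decay

    def step(self, lr: float) -> None:
        for p in self.params:
            if not p.trainable:
                continue
            g = p.grad + self.weight_decay * p.value
            p.value -= lr * g


class RAdam:
    """Rectified Adam: Adam with a variance-rectification warmup.

    While the second-moment estimate is unreliable (rectification term
    rho_t <= 5) the update falls back to unadapted momentum SGD, removing
    the need for a hand-tuned warmup.
    """

    def __init__(self, params: Sequence[Param], betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.rho_inf = 2.0 / (1.0 - self.b2) - 1.0

    def step(self, lr: float) -> None:
        self.t += 1
        t, b1, b2 = self.t, self.b1, self.b2
        rho_t = self.rho_inf - 2.0 * t * b2**t / (1.0 - b2**t)
        for p, m, v in zip(self.params, self.m, self.v):
            if not p.trainable:
                continue
            g = p.grad + self.weight_decay * p.value
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            m_hat = m / (1.0 - b1**t)
            if rho_t > 5.0:
                r = math.sqrt(
                    ((rho_t - 4) * (rho_t - 2) * self.rho_inf)
                    / ((self.rho_inf - 4) * (self.rho_inf - 2) * rho_t)
                )
                v_hat = np.sqrt(v / (1.0 - b2**t))
                p.value -= lr * r * m_hat / (v_hat + self.eps)
            else:
                p.value -= lr * m_hat
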