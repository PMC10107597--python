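"""Parameterized layers and the Adam optimizer used by the model graph."""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor


class Layer:
    """Base class: tracks parameters in creation order."""

    def __init__(self):
        self.params: list[Tensor] = []

    def _param(self, data: np.ndarray) -> Tensor:
        p = ag.parameter(data)
        self.params.append(p)
        return p


class Dense(Layer):
    """Affine map over the last axis."""

    def __init__(self, rng: np.random.Generator, n_in: int, n_out: int):
        super().__init__()
        scale = np.sqrt(2.0 / n_in)
        self.w = self._param(rng.normal(0.0, scale, size=(n_in, n_out)))
        self.b = self._param(np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return ag.dense(x, self.w, self.b)


class Conv2D(Layer):
    def __init__(self, rng: np.random.Generator, c_in: int, c_out: int, k: int = 3, stride: int = 1):
        super().__init__()
        self.stride = stride
        scale = np.sqrt(2.0 / (k * k * c_in))
        self.w = self._param(rng.normal(0.0, scale, size=(k, k, c_in, c_out)))
        self.b = self._param(np.zeros(c_out))

    def __call__(self, x: Tensor) -> Tensor:
        return ag.conv2d(x, self.w, self.b, stride=self.stride)


class Conv1D(Layer):
    def __init__(self, rng: np.random.Generator, c_in: int, c_out: int, k: int = 3, stride: int = 1):
        super().__init__()
        self.stride = stride
        scale = np.sqrt(2.0 / (k * c_in))
        self.w = self._param(rng.normal(0.0, scale, size=(k, c_in, c_out)))
        self.b = self._param(np.zeros(c_out))

    def __call__(self, x: Tensor) -> Tensor:
        return ag.conv1d(x, self.w, self.b, stride=self.stride)


class Adam:
    """Standard Adam on a fixed parameter list."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * p.grad
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * p.grad ** 2
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class SGD:
    def __init__(self, params: list[Tensor], lr: float = 1e-2):
        self.params = params
        self.lr = lr

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        for p in self.params:
            if p.grad is not None:
                p.data -= self.lr * p.grad


def make_optimizer(name: str, params: list[Tensor], lr: float):
    name = name.lower()
    if name == "adam":
        return Adam(params, lr=lr)
    if name == "sgd":
        return SGD(params, lr=lr)
    raise ValueError(f"unknown optimizer {name!r}")
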