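"""Optimizers: Adam and plain SGD."""

from __future__ import annotations

import numpy as np


class SGD:
    def __init__(self, lr: float = 0.001):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.lr = lr

    def step(self, params, grads):
        for p, g in zip(params, grads, strict=True):
            p -= (self.lr * g).astype(p.dtype, copy=False)


class Adam:
    def __init__(self, lr: float = 0.001, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m: list[np.ndarray] | None = None
        self._v: list[np.ndarray] | None = None

    def step(self, params, grads):
        if self._m is None:
            self._m = [np.zeros_like(p) for p in params]
            self._v = [np.zeros_like(p) for p in params]
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1 - b1 ** self.t
        bc2 = 1 - b2 ** self.t
        for p, g, m, v in zip(params, grads, self._m, self._v, strict=True):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * np.square(g)
            p -= (self.lr * (m / bc1)
                  / (np.sqrt(v / bc2) + self.eps)).astype(p.dtype, copy=False)


def make_optimizer(kind: str, lr: float, beta1: float = 0.9,
                   beta2: float = 0.999):
    if kind == "adam":
        return Adam(lr=lr, beta1=beta1, beta2=beta2)
    if kind == "sgd":
        return SGD(lr=lr)
    raise ValueError(f"unknown optimizer {kind!r}")
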