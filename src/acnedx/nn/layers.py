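"""Layer implementations.

Data layout is NHWC throughout.  Each layer caches what its backward
pass needs on forward; ``backward`` returns the gradient w.r.t. the
layer input and fills ``grads`` (aligned with ``params``).
"""

from __future__ import annotations

import numpy as np


class Layer:
    """Base class: a named, optionally trainable computation node."""

    trainable: bool = True
    name: str = "layer"

    @property
    def params(self) -> list[np.ndarray]:
        return []

    @property
    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def output_shape(self, in_shape: tuple) -> tuple:
        raise NotImplementedError


def _pad_same(x: np.ndarray, p: int) -> np.ndarray:
    return np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)), mode="constant")


def _im2col(x: np.ndarray, k: int, buf: np.ndarray | None = None) -> np.ndarray:
    """'same' im2col: (N,H,W,C) -> (N*H*W, k*k*C), tap-major columns.

    Built by k*k strided assignments into one buffer (reused across
    calls when ``buf`` matches) so a single large GEMM does the
    arithmetic.
    """
    n, h, w, c = x.shape
    if (buf is None or buf.shape[0] < n or buf.shape[1:] != (h, w, k * k, c)
            or buf.dtype != x.dtype):
        buf = np.empty((n, h, w, k * k, c), dtype=x.dtype)
    cols = buf[:n]
    j = 0
    xp = _pad_same(x, k // 2)
    for k1 in range(k):
        for k2 in range(k):
            cols[:, :, :, j, :] = xp[:, k1:k1 + h, k2:k2 + w, :]
            j += 1
    return cols, buf


class Conv2D(Layer):
    """Stride-1 'same' convolution with optional ReLU, via im2col."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 ksize: int = 3, activation: str | None = "relu",
                 name: str = "conv"):
        if ksize % 2 != 1:
            raise ValueError("ksize must be odd for 'same' padding")
        self.c_in, self.c_out, self.k = c_in, c_out, ksize
        self.activation = activation
        self.name = name
        fan_in = ksize * ksize * c_in
        # He initialization, suited to ReLU stacks
        self.W = (rng.standard_normal((ksize, ksize, c_in, c_out))
                  * np.sqrt(2.0 / fan_in)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        # set by Sequential on the first layer: its input gradient is
        # never consumed, so the most expensive GEMM can be skipped
        self.skip_input_grad = False
        self._cols_buf = None
        self._dcols_buf = None

    @property
    def params(self):
        return [self.W, self.b]

    @property
    def grads(self):
        return [self.dW, self.db]

    def forward(self, x, train=False, rng=None):
        n, h, w, _ = x.shape
        cols, self._cols_buf = _im2col(x, self.k, self._cols_buf)
        cmat = cols.reshape(n * h * w, -1)
        wmat = self.W.reshape(-1, self.c_out).astype(x.dtype, copy=False)
        z = (cmat @ wmat + self.b).reshape(n, h, w, self.c_out)
        if train:
            self._cols, self._in_shape = cmat, x.shape
        if self.activation == "relu":
            z = np.maximum(z, 0)
            if train:
                self._act_mask = z > 0
        return z

    def backward(self, dout):
        if self.activation == "relu":
            dout = dout * self._act_mask
        n, h, w, _ = self._in_shape
        dmat = np.ascontiguousarray(dout.reshape(n * h * w, self.c_out))
        self.dW = (self._cols.T @ dmat).reshape(self.W.shape).astype(
            self.W.dtype, copy=False)
        self.db = dmat.sum(axis=0).astype(self.b.dtype, copy=False)
        self._cols = None
        if self.skip_input_grad:
            return np.zeros(self._in_shape, dtype=dout.dtype)
        # dX of a stride-1 'same' conv is the 'same' conv of dout with the
        # spatially flipped kernel, in/out channels swapped.
        w_flip = self.W[::-1, ::-1].transpose(0, 1, 3, 2)
        wmat = w_flip.reshape(-1, self.c_in).astype(dout.dtype, copy=False)
        dcols, self._dcols_buf = _im2col(dout, self.k, self._dcols_buf)
        dx = (dcols.reshape(n * h * w, -1) @ wmat).reshape(n, h, w, self.c_in)
        return dx

    def output_shape(self, in_shape):
        return (*in_shape[:-1], self.c_out)


class MaxPool2D(Layer):
    """2x2 stride-2 max pooling.

    ``mode='ceil'`` pads odd edges (output ceil(s/2)); ``mode='floor'``
    drops them (output floor(s/2)).  Gradient at ties is split equally.
    """

    trainable = False

    def __init__(self, mode: str = "ceil", name: str = "pool"):
        if mode not in ("ceil", "floor"):
            raise ValueError(f"unknown pooling mode {mode!r}")
        self.mode = mode
        self.name = name

    def forward(self, x, train=False, rng=None):
        n, h, w, c = x.shape
        if self.mode == "ceil":
            ph, pw = (-h) % 2, (-w) % 2
            if ph or pw:
                x = np.pad(x, ((0, 0), (0, ph), (0, pw), (0, 0)),
                           mode="constant", constant_values=-np.inf)
        else:
            x = x[:, : h - h % 2, : w - w % 2]
        n2, h2, w2, _ = x.shape
        xr = x.reshape(n2, h2 // 2, 2, w2 // 2, 2, c)
        out = xr.max(axis=(2, 4))
        if train:
            self._xr, self._out = xr, out
            self._orig_shape = (n, h, w, c)
        return out

    def backward(self, dout):
        n, h, w, c = self._orig_shape
        mask = self._xr == self._out[:, :, None, :, None, :]
        counts = mask.sum(axis=(2, 4), keepdims=True).astype(dout.dtype)
        dxr = mask * (dout[:, :, None, :, None, :] / counts)
        h2, w2 = self._xr.shape[1] * 2, self._xr.shape[3] * 2
        dx = dxr.reshape(n, h2, w2, c)
        if self.mode == "ceil":
            dx = dx[:, :h, :w]
        else:
            full = np.zeros((n, h, w, c), dtype=dout.dtype)
            full[:, :h2, :w2] = dx
            dx = full
        self._xr = None
        return dx

    def output_shape(self, in_shape):
        n, h, w, c = in_shape
        if self.mode == "ceil":
            return (n, (h + 1) // 2, (w + 1) // 2, c)
        return (n, h // 2, w // 2, c)


class Dropout(Layer):
    """Inverted dropout; identity outside training."""

    trainable = False

    def __init__(self, rate: float = 0.5, name: str = "dropout"):
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.name = name

    def forward(self, x, train=False, rng=None):
        if not train or self.rate == 0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout needs an rng")
        keep = rng.random(x.shape) >= self.rate
        self._mask = keep.astype(x.dtype) / np.asarray(1 - self.rate, x.dtype)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask

    def output_shape(self, in_shape):
        return in_shape


class Flatten(Layer):
    trainable = False

    def __init__(self, name: str = "flatten"):
        self.name = name

    def forward(self, x, train=False, rng=None):
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._in_shape)

    def output_shape(self, in_shape):
        return (in_shape[0], int(np.prod(in_shape[1:])))


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 activation: str | None = None, name: str = "dense"):
        self.n_in, self.n_out = n_in, n_out
        self.activation = activation
        self.name = name
        self.W = (rng.standard_normal((n_in, n_out))
                  * np.sqrt(2.0 / n_in)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    @property
    def params(self):
        return [self.W, self.b]

    @property
    def grads(self):
        return [self.dW, self.db]

    def forward(self, x, train=False, rng=None):
        z = x @ self.W + self.b
        if train:
            self._x = x
        if self.activation == "relu":
            z = np.maximum(z, 0)
            if train:
                self._act_mask = z > 0
        return z

    def backward(self, dout):
        if self.activation == "relu":
            dout = dout * self._act_mask
        self.dW = self._x.T @ dout
        self.db = dout.sum(axis=0)
        dx = dout @ self.W.T
        self._x = None
        return dx

    def output_shape(self, in_shape):
        return (in_shape[0], self.n_out)
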