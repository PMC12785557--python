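"""Minimal trainable CNN layers on NumPy arrays.

All tensors are NHWC float32. Every layer implements ``forward(x, train)``
and ``backward(dout)``; parameters and their gradients live in the
``params`` / ``grads`` dicts so an optimizer can walk them generically.
The implementation favours large BLAS matmuls (im2col) over Python loops,
which keeps desk-scale training of 64x64 patches feasible on one CPU.
"""

from __future__ import annotations

import numpy as np

from ._kernels import col2im_add, im2col_pack

__all__ = [
    "Conv2D",
    "BatchNorm",
    "ReLU",
    "MaxPool2",
    "ConvTranspose2",
    "sigmoid",
]

_F32 = np.float32


def sigmoid(x: np.ndarray) -> np.ndarray:
    """Numerically stable logistic function."""
    out = np.empty_like(x, dtype=_F32)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Layer:
    """Base class: parameter-free layers reuse these empty dicts."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2D(Layer):
    """k x k same-padding convolution, stride 1, He-initialised.

    Weight layout is ``(k*k*cin, cout)`` with the window offset as the
    leading flat index, so im2col reduces to k*k cheap slice copies and
    the convolution itself is one large BLAS matmul.
    """

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        super().__init__()
        self.cin, self.cout, self.k = cin, cout, k
        fan_in = cin * k * k
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, cout))
        self.params = {"W": w.astype(_F32), "b": np.zeros(cout, _F32)}
        self._cols: np.ndarray | None = None
        self._xshape: tuple[int, ...] | None = None

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        k = self.k
        if k == 1:
            return np.ascontiguousarray(x, dtype=_F32).reshape(n * h * w, c)
        p = k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0))) if p else x
        return im2col_pack(np.ascontiguousarray(xp, dtype=_F32), k, h, w)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, h, w, _ = x.shape
        cols = self._im2col(x)
        out = cols @ self.params["W"] + self.params["b"]
        if train:
            self._cols = cols
            self._xshape = x.shape
        return out.reshape(n, h, w, self.cout)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        assert self._cols is not None and self._xshape is not None
        n, h, w, _ = self._xshape
        dflat = dout.reshape(n * h * w, self.cout)
        self.grads["W"] = self._cols.T @ dflat
        self.grads["b"] = dflat.sum(axis=0)
        dcols = dflat @ self.params["W"].T
        self._cols = None
        k, c = self.k, self.cin
        if k == 1:
            return dcols.reshape(n, h, w, c)
        p = k // 2
        dxp = col2im_add(dcols, k, n, h, w, c)
        return dxp[:, p : p + h, p : p + w, :] if p else dxp


class BatchNorm(Layer):
    """Per-channel batch normalisation over (N, H, W)."""

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.params = {"gamma": np.ones(c, _F32), "beta": np.zeros(c, _F32)}
        self.running_mean = np.zeros(c, _F32)
        self.running_var = np.ones(c, _F32)
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mean
            ).astype(_F32)
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            ).astype(_F32)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        if train:
            self._cache = (xhat.astype(_F32), inv.astype(_F32))
        return (self.params["gamma"] * xhat + self.params["beta"]).astype(_F32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        assert self._cache is not None
        xhat, inv = self._cache
        self._cache = None
        m = dout.shape[0] * dout.shape[1] * dout.shape[2]
        self.grads["gamma"] = (dout * xhat).sum(axis=(0, 1, 2))
        self.grads["beta"] = dout.sum(axis=(0, 1, 2))
        dxhat = dout * self.params["gamma"]
        # standard batchnorm backward, vectorised per channel
        dx = (
            inv
            / m
            * (
                m * dxhat
                - dxhat.sum(axis=(0, 1, 2))
                - xhat * (dxhat * xhat).sum(axis=(0, 1, 2))
            )
        )
        return dx.astype(_F32)


class ReLU(Layer):
    def __init__(self) -> None:
        super().__init__()
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        assert self._mask is not None
        dx = dout * self._mask
        self._mask = None
        return dx


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; ties route the gradient to the first max."""

    def __init__(self) -> None:
        super().__init__()
        self._argmax: np.ndarray | None = None
        self._inshape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, h, w, c = x.shape
        quads = np.stack(
            [x[:, 0::2, 0::2], x[:, 0::2, 1::2], x[:, 1::2, 0::2], x[:, 1::2, 1::2]],
            axis=-1,
        )
        if train:
            self._argmax = quads.argmax(axis=-1).astype(np.int8)
            self._inshape = x.shape
        return quads.max(axis=-1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        assert self._argmax is not None and self._inshape is not None
        n, h, w, c = self._inshape
        dx = np.zeros((n, h, w, c), _F32)
        views = [dx[:, 0::2, 0::2], dx[:, 0::2, 1::2], dx[:, 1::2, 0::2], dx[:, 1::2, 1::2]]
        for q, view in enumerate(views):
            sel = self._argmax == q
            view[sel] = dout[sel]
        self._argmax = None
        return dx


class ConvTranspose2(Layer):
    """2x2 transposed convolution with stride 2 (exact 2x upsampling).

    With kernel == stride the output blocks do not overlap, so the op is a
    per-pixel matmul followed by a block reshape.
    """

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        super().__init__()
        self.cin, self.cout = cin, cout
        w = rng.normal(0.0, np.sqrt(2.0 / cin), size=(cin, 4 * cout))
        self.params = {"W": w.astype(_F32), "b": np.zeros(cout, _F32)}
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, h, w, _ = x.shape
        y = x.reshape(n * h * w, self.cin) @ self.params["W"]
        y = y.reshape(n, h, w, 2, 2, self.cout).transpose(0, 1, 3, 2, 4, 5)
        if train:
            self._x = x
        return np.ascontiguousarray(y).reshape(n, 2 * h, 2 * w, self.cout) + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        assert self._x is not None
        x = self._x
        self._x = None
        n, h, w, _ = x.shape
        d = dout.reshape(n, h, 2, w, 2, self.cout).transpose(0, 1, 3, 2, 4, 5)
        dflat = np.ascontiguousarray(d).reshape(n * h * w, 4 * self.cout)
        self.grads["W"] = x.reshape(n * h * w, self.cin).T @ dflat
        self.grads["b"] = dout.sum(axis=(0, 1, 2))
        dx = dflat @ self.params["W"].T
        return dx.reshape(n, h, w, self.cin)
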