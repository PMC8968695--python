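"""Minimal reverse-mode automatic differentiation on NumPy arrays.

A :class:`Tensor` wraps a float32 ndarray and records the operations applied
to it on a tape; :meth:`Tensor.backward` replays the tape in reverse
topological order.  Only the primitives the segmentation networks need are
provided: broadcast arithmetic, reductions, 'same'-padded 2D convolution
(via im2col + GEMM), 2x2 max pooling, nearest-neighbor 2x upsampling,
channel concatenation, and the pointwise nonlinearities.  Weight sharing
(as in recurrent convolutions) is handled naturally by gradient
accumulation.

All gradient formulas are exercised against central finite differences in
the test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor", "Parameter", "as_tensor", "concat", "conv2d", "maxpool2x2",
    "upsample2x", "leaky_relu", "sigmoid", "log_softmax", "softmax",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the computation graph."""

    __slots__ = ("data", "grad", "_parents", "_grad_fn")

    def __init__(self, data, _parents=(), _grad_fn=None):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self._parents = _parents
        self._grad_fn = _grad_fn

    # ---- introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.shape})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # ---- autograd ------------------------------------------------------
    def backward(self):
        topo, seen = [], set()

        def visit(node):
            if id(node) in seen:
                return
            seen.add(id(node))
            for p in node._parents:
                visit(p)
            topo.append(node)

        visit(self)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._grad_fn is None or node.grad is None:
                continue
            for parent, g in zip(node._parents, node._grad_fn(node.grad)):
                if g is None:
                    continue
                if parent.grad is None:
                    parent.grad = g.astype(np.float32, copy=False)
                else:
                    parent.grad = parent.grad + g

    # ---- arithmetic ----------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data, (self, other))
        out._grad_fn = lambda g: (
            _unbroadcast(g, self.shape), _unbroadcast(g, other.shape))
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, (self,))
        out._grad_fn = lambda g: (-g,)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data, (self, other))
        out._grad_fn = lambda g: (
            _unbroadcast(g * other.data, self.shape),
            _unbroadcast(g * self.data, other.shape),
        )
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data / other.data, (self, other))
        out._grad_fn = lambda g: (
            _unbroadcast(g / other.data, self.shape),
            _unbroadcast(-g * self.data / (other.data ** 2), other.shape),
        )
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, n: float):
        out = Tensor(self.data ** n, (self,))
        out._grad_fn = lambda g: (g * n * self.data ** (n - 1),)
        return out

    # ---- shape ops -----------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape
        out = Tensor(self.data.reshape(shape), (self,))
        out._grad_fn = lambda g: (g.reshape(old),)
        return out

    # ---- reductions ----------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), (self,))
        shape = self.shape

        def grad_fn(g):
            if axis is None:
                return (np.broadcast_to(g, shape).copy(),)
            ax = axis if isinstance(axis, tuple) else (axis,)
            if not keepdims:
                g = np.expand_dims(g, ax)
            return (np.broadcast_to(g, shape).copy(),)

        out._grad_fn = grad_fn
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # ---- pointwise -----------------------------------------------------
    def exp(self):
        e = np.exp(self.data)
        out = Tensor(e, (self,))
        out._grad_fn = lambda g: (g * e,)
        return out

    def log(self):
        out = Tensor(np.log(self.data), (self,))
        out._grad_fn = lambda g: (g / self.data,)
        return out


class Parameter(Tensor):
    """A trainable leaf tensor."""

    __slots__ = ()


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 tuple(tensors))
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]
    out._grad_fn = lambda g: tuple(np.split(g, splits, axis=axis))
    return out


def leaky_relu(x: Tensor, slope: float = 0.01) -> Tensor:
    x = as_tensor(x)
    mask = x.data >= 0
    out = Tensor(np.where(mask, x.data, slope * x.data), (x,))
    out._grad_fn = lambda g: (np.where(mask, g, slope * g),)
    return out


def sigmoid(x: Tensor) -> Tensor:
    x = as_tensor(x)
    d = x.data
    s = np.where(d >= 0, 1.0 / (1.0 + np.exp(-np.abs(d))),
                 np.exp(-np.abs(d)) / (1.0 + np.exp(-np.abs(d))))
    out = Tensor(s, (x,))
    out._grad_fn = lambda g: (g * s * (1.0 - s),)
    return out


def log_softmax(x: Tensor, axis: int = 1) -> Tensor:
    # subtracting the (detached) max is gradient-neutral and stabilizes exp
    m = Tensor(x.data.max(axis=axis, keepdims=True))
    y = x - m
    return y - y.exp().sum(axis=axis, keepdims=True).log()


def softmax(x: Tensor, axis: int = 1) -> Tensor:
    return log_softmax(x, axis=axis).exp()


# ---- spatial primitives (NCHW layout) ----------------------------------

def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """'Same'-padded stride-1 2D convolution (cross-correlation).

    x: (N, C, H, W); w: (O, C, k, k) with odd k; b: (O,) or None.
    """
    x, w = as_tensor(x), as_tensor(w)
    n, c, H, W = x.shape
    o = w.shape[0]
    k = w.shape[2]
    p = k // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)))
    # im2col: one contiguous (N*H*W, C*k*k) matrix, reused in backward
    cols = sliding_window_view(xp, (k, k), axis=(2, 3))
    cols_mat = np.ascontiguousarray(
        cols.transpose(0, 2, 3, 1, 4, 5)).reshape(n * H * W, c * k * k)
    w_mat = w.data.reshape(o, -1)
    out_data = (cols_mat @ w_mat.T).reshape(n, H, W, o).transpose(0, 3, 1, 2)
    out_data = np.ascontiguousarray(out_data)
    if b is not None:
        out_data += b.data[None, :, None, None]
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(out_data, parents)

    def grad_fn(g):
        g_mat = np.ascontiguousarray(
            g.transpose(0, 2, 3, 1)).reshape(n * H * W, o)
        dw = (g_mat.T @ cols_mat).reshape(w.shape)
        # col2im: scatter-add the column gradients back onto the padded input
        dcols = (g_mat @ w_mat).reshape(n, H, W, c, k, k)
        dxp = np.zeros_like(xp)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + H, j:j + W] += dcols[:, :, :, :, i, j
                                                     ].transpose(0, 3, 1, 2)
        dx = dxp[:, :, p:p + H, p:p + W] if p else dxp
        if b is None:
            return dx, dw
        return dx, dw, g.sum(axis=(0, 2, 3))

    out._grad_fn = grad_fn
    return out


def maxpool2x2(x: Tensor) -> Tensor:
    """2x2 max pooling with stride 2; spatial dims must be even."""
    x = as_tensor(x)
    n, c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError(f"maxpool2x2 needs even spatial dims, got {h}x{w}")
    r = x.data.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    r = r.reshape(n, c, h // 2, w // 2, 4)
    idx = r.argmax(axis=-1)
    out = Tensor(np.take_along_axis(r, idx[..., None], axis=-1)[..., 0], (x,))

    def grad_fn(g):
        dr = np.zeros((n, c, h // 2, w // 2, 4), dtype=g.dtype)
        np.put_along_axis(dr, idx[..., None], g[..., None], axis=-1)
        dr = dr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return (dr.reshape(n, c, h, w),)

    out._grad_fn = grad_fn
    return out


def upsample2x(x: Tensor) -> Tensor:
    """Nearest-neighbor 2x spatial upsampling."""
    x = as_tensor(x)
    n, c, h, w = x.shape
    out = Tensor(np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3), (x,))
    out._grad_fn = lambda g: (
        g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)),)
    return out
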