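"""Minimal reverse-mode automatic differentiation over numpy arrays.

A ``Tensor`` wraps an ndarray and records the operation that produced it;
``backward()`` walks the graph in reverse topological order and accumulates
gradients.  Only the operations needed by the denoiser network are provided
(broadcast arithmetic, batched matmul, reshape/transpose, reductions,
2-D convolution with reflection padding, pooling/upsampling, softmax, SiLU).
Every primitive's gradient is checked against central finite differences in
the test suite.
"""

from __future__ import annotations

import math
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "add",
    "mul",
    "matmul",
    "reshape",
    "transpose",
    "tsum",
    "tmean",
    "power",
    "silu",
    "sigmoid",
    "softmax",
    "concat",
    "reflect_pad2d",
    "conv2d_valid",
    "avg_pool2d",
    "upsample_nearest2d",
]


class Tensor:
    """An ndarray node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], None] | None = None

    # -- graph bookkeeping -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: deep U-nets overflow Python recursion
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(self.data.dtype, copy=True)
        else:
            self.grad += grad

    # -- operator sugar ----------------------------------------------------
    def _coerce(self, other) -> "Tensor":
        if isinstance(other, Tensor):
            return other
        # keep python scalars from upcasting float32 graphs
        return Tensor(np.asarray(other, dtype=self.data.dtype))

    def __add__(self, other):
        return add(self, self._coerce(other))

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, self._coerce(other))

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, Tensor(np.array(-1.0, dtype=self.data.dtype)))

    def __sub__(self, other):
        return add(self, -self._coerce(other))

    def __rsub__(self, other):
        return add(self._coerce(other), -self)

    def __matmul__(self, other):
        return matmul(self, as_tensor(other))

    def __pow__(self, exponent: float):
        return power(self, exponent)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def transpose(self, *axes):
        return transpose(self, axes if len(axes) > 1 else axes[0])

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _make(data, parents: Sequence[Tensor], backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad or p._parents for p in parents):
        out.requires_grad = any(p.requires_grad for p in parents)
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce a broadcast gradient back to the operand's shape."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


# -- arithmetic -------------------------------------------------------------


def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def backward(g):
        a._accumulate(_unbroadcast(g, a.shape))
        b._accumulate(_unbroadcast(g, b.shape))

    return _make(out_data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data

    def backward(g):
        a._accumulate(_unbroadcast(g * b.data, a.shape))
        b._accumulate(_unbroadcast(g * a.data, b.shape))

    return _make(out_data, (a, b), backward)


def power(a: Tensor, exponent: float) -> Tensor:
    out_data = a.data**exponent

    def backward(g):
        a._accumulate(g * exponent * a.data ** (exponent - 1))

    return _make(out_data, (a,), backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data @ b.data

    def backward(g):
        ga = g @ np.swapaxes(b.data, -1, -2)
        gb = np.swapaxes(a.data, -1, -2) @ g
        a._accumulate(_unbroadcast(ga, a.shape))
        b._accumulate(_unbroadcast(gb, b.shape))

    return _make(out_data, (a, b), backward)


# -- shape ------------------------------------------------------------------


def reshape(a: Tensor, shape) -> Tensor:
    orig = a.shape
    out_data = a.data.reshape(shape)

    def backward(g):
        a._accumulate(g.reshape(orig))

    return _make(out_data, (a,), backward)


def transpose(a: Tensor, axes) -> Tensor:
    axes = tuple(axes)
    inv = tuple(np.argsort(axes))
    out_data = a.data.transpose(axes)

    def backward(g):
        a._accumulate(g.transpose(inv))

    return _make(out_data, (a,), backward)


def concat(tensors: Iterable[Tensor], axis: int) -> Tensor:
    tensors = list(tensors)
    sizes = [t.shape[axis] for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            t._accumulate(g[tuple(idx)])

    return _make(out_data, tensors, backward)


# -- reductions -------------------------------------------------------------


def tsum(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if axis is None:
            grad = np.broadcast_to(g, a.shape)
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            if not keepdims:
                g = np.expand_dims(g, axes)
            grad = np.broadcast_to(g, a.shape)
        a._accumulate(np.ascontiguousarray(grad))

    return _make(out_data, (a,), backward)


def tmean(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    if axis is None:
        count = a.data.size
    else:
        axes = (axis,) if isinstance(axis, int) else tuple(axis)
        count = math.prod(a.shape[ax] for ax in axes)
    s = tsum(a, axis=axis, keepdims=keepdims)
    return mul(s, as_tensor(np.array(1.0 / count, dtype=a.data.dtype)))


# -- nonlinearities ---------------------------------------------------------


def sigmoid(a: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-a.data))

    def backward(g):
        a._accumulate(g * s * (1.0 - s))

    return _make(s, (a,), backward)


def silu(a: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-a.data))
    out_data = a.data * s

    def backward(g):
        a._accumulate(g * s * (1.0 + a.data * (1.0 - s)))

    return _make(out_data, (a,), backward)


def softmax(a: Tensor, axis: int = -1) -> Tensor:
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    y = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * y).sum(axis=axis, keepdims=True)
        a._accumulate(y * (g - dot))

    return _make(y, (a,), backward)


# -- 2-D image primitives (NCHW) --------------------------------------------


def reflect_pad2d(a: Tensor, pad: int) -> Tensor:
    if pad == 0:
        return a
    out_data = np.pad(a.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)), mode="reflect")
    H, W = a.shape[-2:]
    # reflection index maps: padded position -> source position
    row_idx = np.pad(np.arange(H), pad, mode="reflect")
    col_idx = np.pad(np.arange(W), pad, mode="reflect")

    def backward(g):
        grad = np.zeros(a.shape, dtype=g.dtype)
        # scatter-add rows then columns
        tmp = np.zeros(a.shape[:2] + (H, g.shape[-1]), dtype=g.dtype)
        np.add.at(tmp, (slice(None), slice(None), row_idx), g)
        np.add.at(
            grad.transpose(0, 1, 3, 2),
            (slice(None), slice(None), col_idx),
            tmp.transpose(0, 1, 3, 2),
        )
        a._accumulate(grad)

    return _make(out_data, (a,), backward)


def _im2col(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    # (B, C, H, W) -> (B, C, Ho, Wo, kh, kw) view
    return np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))


def conv2d_valid(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Stride-1 'valid' cross-correlation; pad beforehand for 'same' output."""
    kh, kw = w.shape[-2:]
    cols = _im2col(x.data, kh, kw)
    out_data = np.einsum("bchwij,ocij->bohw", cols, w.data, optimize=True)
    if b is not None:
        out_data = out_data + b.data[None, :, None, None]

    def backward(g):
        gw = np.einsum("bohw,bchwij->ocij", g, cols, optimize=True)
        w._accumulate(gw)
        if b is not None:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        gp = np.pad(g, ((0, 0), (0, 0), (kh - 1, kh - 1), (kw - 1, kw - 1)))
        gcols = _im2col(gp, kh, kw)
        w_rot = w.data[:, :, ::-1, ::-1]
        gx = np.einsum("bohwij,ocij->bchw", gcols, w_rot, optimize=True)
        x._accumulate(gx)

    parents = (x, w) if b is None else (x, w, b)
    return _make(out_data, parents, backward)


def avg_pool2d(a: Tensor, k: int = 2) -> Tensor:
    B, C, H, W = a.shape
    if H % k or W % k:
        raise ValueError(f"spatial size {(H, W)} not divisible by pool size {k}")
    out_data = a.data.reshape(B, C, H // k, k, W // k, k).mean(axis=(3, 5))

    def backward(g):
        grad = np.repeat(np.repeat(g, k, axis=2), k, axis=3) / (k * k)
        a._accumulate(grad)

    return _make(out_data, (a,), backward)


def upsample_nearest2d(a: Tensor, k: int = 2) -> Tensor:
    out_data = np.repeat(np.repeat(a.data, k, axis=2), k, axis=3)

    def backward(g):
        B, C, H, W = a.shape
        grad = g.reshape(B, C, H, k, W, k).sum(axis=(3, 5))
        a._accumulate(grad)

    return _make(out_data, (a,), backward)
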