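"""Minimal reverse-mode automatic differentiation over numpy arrays.

A tiny tape-based engine sufficient for the networks in this package:
broadcasting arithmetic, (batched) matrix products, element-wise
nonlinearities, reductions, reshapes, slicing, concatenation, softmax and a
3-D convolution primitive.  Gradients are accumulated into ``Tensor.grad``
by :meth:`Tensor.backward` in reverse topological order.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Sequence

import numpy as np

__all__ = ["Tensor", "Parameter", "no_grad", "concat", "conv3d", "softmax"]

_grad_enabled = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction inside the context (inference mode)."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast to reach ``grad.shape``."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A numpy array plus an optional gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = data if isinstance(data, np.ndarray) else np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], None] | None = None

    # ------------------------------------------------------------------ infra
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = _as_tensor(other, like=self)
        out = _make(self.data + other.data, (self, other))
        if out._backward is _PENDING:
            def backward(g):
                if self.requires_grad:
                    self._accumulate(_unbroadcast(g, self.data.shape))
                if other.requires_grad:
                    other._accumulate(_unbroadcast(g, other.data.shape))
            out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = _make(-self.data, (self,))
        if out._backward is _PENDING:
            out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-_as_tensor(other, like=self))

    def __rsub__(self, other):
        return _as_tensor(other, like=self) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other, like=self)
        out = _make(self.data * other.data, (self, other))
        if out._backward is _PENDING:
            def backward(g):
                if self.requires_grad:
                    self._accumulate(_unbroadcast(g * other.data, self.data.shape))
                if other.requires_grad:
                    other._accumulate(_unbroadcast(g * self.data, other.data.shape))
            out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other, like=self)
        return self * (other ** -1.0)

    def __rtruediv__(self, other):
        return _as_tensor(other, like=self) * (self ** -1.0)

    def __pow__(self, exponent: float):
        out = _make(self.data ** exponent, (self,))
        if out._backward is _PENDING:
            def backward(g):
                self._accumulate(g * exponent * self.data ** (exponent - 1.0))
            out._backward = backward
        return out

    def __matmul__(self, other):
        other = _as_tensor(other, like=self)
        out = _make(self.data @ other.data, (self, other))
        if out._backward is _PENDING:
            a, b = self.data, other.data
            def backward(g):
                if self.requires_grad:
                    self._accumulate(_unbroadcast(g @ b.swapaxes(-1, -2), a.shape))
                if other.requires_grad:
                    other._accumulate(_unbroadcast(a.swapaxes(-1, -2) @ g, b.shape))
            out._backward = backward
        return out

    # ----------------------------------------------------------- element-wise
    def exp(self):
        e = np.exp(self.data)
        out = _make(e, (self,))
        if out._backward is _PENDING:
            out._backward = lambda g: self._accumulate(g * e)
        return out

    def log(self):
        out = _make(np.log(self.data), (self,))
        if out._backward is _PENDING:
            out._backward = lambda g: self._accumulate(g / self.data)
        return out

    def sqrt(self):
        r = np.sqrt(self.data)
        out = _make(r, (self,))
        if out._backward is _PENDING:
            out._backward = lambda g: self._accumulate(g * 0.5 / r)
        return out

    def relu(self):
        mask = self.data > 0
        out = _make(np.where(mask, self.data, 0.0), (self,))
        if out._backward is _PENDING:
            out._backward = lambda g: self._accumulate(g * mask)
        return out

    def leaky_relu(self, slope: float = 0.2):
        mask = self.data > 0
        out = _make(np.where(mask, self.data, slope * self.data), (self,))
        if out._backward is _PENDING:
            out._backward = lambda g: self._accumulate(g * np.where(mask, 1.0, slope))
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = _make(s, (self,))
        if out._backward is _PENDING:
            out._backward = lambda g: self._accumulate(g * s * (1.0 - s))
        return out

    def abs(self):
        sgn = np.sign(self.data)
        out = _make(np.abs(self.data), (self,))
        if out._backward is _PENDING:
            out._backward = lambda g: self._accumulate(g * sgn)
        return out

    def clip_min(self, lo: float):
        """max(x, lo) element-wise; gradient passes where x > lo."""
        mask = self.data > lo
        out = _make(np.where(mask, self.data, lo), (self,))
        if out._backward is _PENDING:
            out._backward = lambda g: self._accumulate(g * mask)
        return out

    # ------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        out = _make(self.data.sum(axis=axis, keepdims=keepdims), (self,))
        if out._backward is _PENDING:
            def backward(g):
                if axis is None:
                    self._accumulate(np.broadcast_to(g, self.data.shape))
                    return
                axes = (axis,) if isinstance(axis, int) else tuple(axis)
                if not keepdims:
                    for ax in sorted(a % self.data.ndim for a in axes):
                        g = np.expand_dims(g, ax)
                self._accumulate(np.broadcast_to(g, self.data.shape))
            out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -------------------------------------------------------------- structure
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = _make(self.data.reshape(shape), (self,))
        if out._backward is _PENDING:
            out._backward = lambda g: self._accumulate(g.reshape(self.data.shape))
        return out

    def transpose(self, *axes):
        if not axes:
            axes = tuple(reversed(range(self.data.ndim)))
        elif len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = _make(self.data.transpose(axes), (self,))
        if out._backward is _PENDING:
            out._backward = lambda g: self._accumulate(g.transpose(inv))
        return out

    @property
    def T(self):
        return self.transpose()

    def __getitem__(self, idx):
        out = _make(self.data[idx], (self,))
        if out._backward is _PENDING:
            def backward(g):
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accumulate(full)
            out._backward = backward
        return out

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


class Parameter(Tensor):
    """A trainable tensor (always requires grad)."""

    __slots__ = ()

    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


def _PENDING(_g):  # sentinel marking "needs a backward closure"
    raise RuntimeError("backward closure not attached")


def _make(data: np.ndarray, parents: Sequence[Tensor]) -> Tensor:
    req = _grad_enabled and any(p.requires_grad for p in parents)
    out = Tensor(data, requires_grad=req)
    if req:
        out._parents = tuple(p for p in parents if p.requires_grad)
        out._backward = _PENDING
    return out


def _as_tensor(x, like: Tensor | None = None) -> Tensor:
    if isinstance(x, Tensor):
        return x
    dtype = like.data.dtype if like is not None else np.float64
    return Tensor(np.asarray(x, dtype=dtype))


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [t if isinstance(t, Tensor) else Tensor(np.asarray(t)) for t in tensors]
    out = _make(np.concatenate([t.data for t in tensors], axis=axis), tensors)
    if out._backward is _PENDING:
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]
        def backward(g):
            for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
                if t.requires_grad:
                    t._accumulate(piece)
        out._backward = backward
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    m = x.data.max(axis=axis, keepdims=True)
    e = np.exp(x.data - m)
    s = e / e.sum(axis=axis, keepdims=True)
    out = _make(s, (x,))
    if out._backward is _PENDING:
        def backward(g):
            dot = (g * s).sum(axis=axis, keepdims=True)
            x._accumulate(s * (g - dot))
        out._backward = backward
    return out


def conv3d(x: Tensor, w: Tensor, b: Tensor | None = None, padding: int = 1) -> Tensor:
    """3-D convolution, stride 1.

    ``x``: (B, C_in, X, Y, Z); ``w``: (C_out, C_in, k, k, k); ``b``: (C_out,).
    Implemented as im2col + matmul; the column matrix is kept for the
    backward pass.
    """
    B, Ci, X, Y, Z = x.data.shape
    Co, Ci2, k1, k2, k3 = w.data.shape
    if Ci != Ci2:
        raise ValueError(f"channel mismatch: input {Ci}, kernel {Ci2}")
    p = padding
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p), (p, p))) if p else x.data
    win = np.lib.stride_tricks.sliding_window_view(xp, (k1, k2, k3), axis=(2, 3, 4))
    Xo, Yo, Zo = win.shape[2:5]
    V = Xo * Yo * Zo
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 4, 1, 5, 6, 7)).reshape(B, V, Ci * k1 * k2 * k3)
    wmat = w.data.reshape(Co, -1).T
    out_flat = cols @ wmat
    if b is not None:
        out_flat += b.data
    out_data = np.ascontiguousarray(out_flat.transpose(0, 2, 1)).reshape(B, Co, Xo, Yo, Zo)
    parents = (x, w) if b is None else (x, w, b)
    out = _make(out_data, parents)
    if out._backward is _PENDING:
        def backward(g):
            gf = np.ascontiguousarray(g.reshape(B, Co, V).transpose(0, 2, 1))  # (B, V, Co)
            if b is not None and b.requires_grad:
                b._accumulate(gf.sum(axis=(0, 1)))
            if w.requires_grad:
                dw = cols.reshape(B * V, -1).T @ gf.reshape(B * V, Co)
                w._accumulate(dw.T.reshape(w.data.shape))
            if x.requires_grad:
                dcols = gf @ wmat.T  # (B, V, Ci*k^3)
                dwin = dcols.reshape(B, Xo, Yo, Zo, Ci, k1, k2, k3).transpose(0, 4, 1, 2, 3, 5, 6, 7)
                gpad = np.zeros_like(xp)
                for i in range(k1):
                    for j in range(k2):
                        for k in range(k3):
                            gpad[:, :, i:i + Xo, j:j + Yo, k:k + Zo] += dwin[..., i, j, k]
                x._accumulate(gpad[:, :, p:p + X, p:p + Y, p:p + Z] if p else gpad)
        out._backward = backward
    return out
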