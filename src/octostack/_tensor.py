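"""Minimal reverse-mode automatic differentiation on numpy arrays.

This is the numerical core the segmentation network and the differentiable
losses are built on: a :class:`Tensor` wrapping an ``ndarray``, a small set of
primitive operations with hand-written vector-Jacobian products, and a
topological-order backward pass.  Only the operations the package actually
needs exist here (elementwise arithmetic with broadcasting, reductions,
2-D convolution, bilinear resampling, gather, concatenation); it is not a
general framework.

Gradients are accumulated into ``Tensor.grad`` as plain numpy arrays.  A
module-level switch (:func:`no_grad`) disables graph construction for
inference passes.
"""

from __future__ import annotations

import contextlib
from typing import Iterable, Sequence

import numpy as np

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Context manager that disables autograd graph construction."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
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
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data)
        if self.data.dtype.kind not in "fc":
            self.data = self.data.astype(np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev: tuple = ()

    # -- graph construction -------------------------------------------------

    @staticmethod
    def _result(data, parents: Sequence["Tensor"], backward):
        out = Tensor.__new__(Tensor)
        out.data = data
        out.grad = None
        out._backward = None
        out._prev = ()
        out.requires_grad = _GRAD_ENABLED and any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._backward = backward
            out._prev = tuple(parents)
        return out

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data, dtype=np.result_type(self.data, np.float32))
        self.grad += g

    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self._accum(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- basic properties ---------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- elementwise arithmetic ---------------------------------------------

    def __add__(self, other):
        other = as_tensor(other)
        out_data = self.data + other.data

        def backward(go):
            if self.requires_grad:
                self._accum(_unbroadcast(go, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(go, other.data.shape))

        return Tensor._result(out_data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = as_tensor(other)
        out_data = self.data * other.data

        def backward(go):
            if self.requires_grad:
                self._accum(_unbroadcast(go * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(go * self.data, other.data.shape))

        return Tensor._result(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __truediv__(self, other):
        other = as_tensor(other)
        out_data = self.data / other.data

        def backward(go):
            if self.requires_grad:
                self._accum(_unbroadcast(go / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-go * self.data / (other.data ** 2),
                                          other.data.shape))

        return Tensor._result(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        out_data = self.data ** exponent

        def backward(go):
            if self.requires_grad:
                self._accum(go * exponent * self.data ** (exponent - 1))

        return Tensor._result(out_data, (self,), backward)

    # -- elementwise nonlinearities ------------------------------------------

    def exp(self):
        out_data = np.exp(self.data)

        def backward(go):
            if self.requires_grad:
                self._accum(go * out_data)

        return Tensor._result(out_data, (self,), backward)

    def log(self):
        out_data = np.log(self.data)

        def backward(go):
            if self.requires_grad:
                self._accum(go / self.data)

        return Tensor._result(out_data, (self,), backward)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(go):
            if self.requires_grad:
                self._accum(go * 0.5 / out_data)

        return Tensor._result(out_data, (self,), backward)

    def relu(self):
        mask = self.data > 0
        out_data = np.where(mask, self.data, 0.0)

        def backward(go):
            if self.requires_grad:
                self._accum(go * mask)

        return Tensor._result(out_data, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(go):
            if self.requires_grad:
                self._accum(go * out_data * (1.0 - out_data))

        return Tensor._result(out_data, (self,), backward)

    def abs(self):
        sign = np.sign(self.data)
        out_data = np.abs(self.data)

        def backward(go):
            if self.requires_grad:
                self._accum(go * sign)

        return Tensor._result(out_data, (self,), backward)

    # -- reductions ----------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(go):
            if not self.requires_grad:
                return
            g = np.asarray(go)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        return Tensor._result(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False):
        """Max along one axis; gradient routed to the first arg-max entries."""
        out_data = self.data.max(axis=axis, keepdims=keepdims)
        idx = self.data.argmax(axis=axis)

        def backward(go):
            if not self.requires_grad:
                return
            g = np.asarray(go)
            if keepdims:
                g = np.squeeze(g, axis=axis)
            grad = np.zeros_like(self.data)
            np.put_along_axis(grad, np.expand_dims(idx, axis),
                              np.expand_dims(g, axis), axis=axis)
            self._accum(grad)

        return Tensor._result(out_data, (self,), backward)

    # -- shape manipulation ----------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        out_data = self.data.reshape(shape)

        def backward(go):
            if self.requires_grad:
                self._accum(go.reshape(old))

        return Tensor._result(out_data, (self,), backward)

    def flatten(self):
        return self.reshape(-1)

    def take(self, indices: np.ndarray):
        """Gather from a flat tensor (used by the sorted-error losses)."""
        indices = np.asarray(indices)
        out_data = self.data[indices]

        def backward(go):
            if self.requires_grad:
                grad = np.zeros_like(self.data)
                np.add.at(grad, indices, go)
                self._accum(grad)

        return Tensor._result(out_data, (self,), backward)

    def __getitem__(self, key):
        out_data = self.data[key]

        def backward(go):
            if self.requires_grad:
                grad = np.zeros_like(self.data)
                np.add.at(grad, key, go)
                self._accum(grad)

        return Tensor._result(out_data, (self,), backward)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(go):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * go.ndim
                sl[axis] = slice(lo, hi)
                t._accum(go[tuple(sl)])

    return Tensor._result(out_data, tuple(tensors), backward)


def softmax(x: Tensor, axis: int = 0) -> Tensor:
    """Numerically stable softmax along `axis` (shift is constant, so exact)."""
    shift = x.data.max(axis=axis, keepdims=True)
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


# -- spatial primitives --------------------------------------------------------


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2-D cross-correlation, NCHW layout, square stride/padding.

    Forward via a strided sliding-window view + einsum; backward accumulates
    the input gradient with one small einsum per kernel tap.
    """
    xd, wd = x.data, w.data
    n, cin, h, wdt = xd.shape
    cout, cin2, kh, kw = wd.shape
    if cin != cin2:
        raise ValueError(f"conv2d: input has {cin} channels, kernel expects {cin2}")
    if padding:
        xp = np.pad(xd, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    else:
        xp = xd
    s = stride
    ho = (xp.shape[2] - kh) // s + 1
    wo = (xp.shape[3] - kw) // s + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    win = win[:, :, ::s, ::s]
    # im2col: (N*Ho*Wo, Cin*kh*kw) @ (Cin*kh*kw, Cout)
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5))
    cols = cols.reshape(n * ho * wo, cin * kh * kw)
    wmat = wd.reshape(cout, -1)
    out_flat = cols @ wmat.T
    if b is not None:
        out_flat = out_flat + b.data
    out_data = np.ascontiguousarray(
        out_flat.reshape(n, ho, wo, cout).transpose(0, 3, 1, 2))
    parents = (x, w) if b is None else (x, w, b)

    def backward(go):
        gom = np.ascontiguousarray(go.transpose(0, 2, 3, 1)).reshape(-1, cout)
        if w.requires_grad:
            w._accum((gom.T @ cols).reshape(wd.shape))
        if b is not None and b.requires_grad:
            b._accum(gom.sum(axis=0))
        if x.requires_grad:
            gcols = (gom @ wmat).reshape(n, ho, wo, cin, kh, kw)
            gxp = np.zeros_like(xp)
            for k in range(kh):
                for l in range(kw):
                    gxp[:, :, k:k + (ho - 1) * s + 1:s,
                        l:l + (wo - 1) * s + 1:s] += \
                        gcols[:, :, :, :, k, l].transpose(0, 3, 1, 2)
            if padding:
                gxp = gxp[:, :, padding:padding + h, padding:padding + wdt]
            x._accum(gxp)

    return Tensor._result(out_data, parents, backward)


_INTERP_CACHE: dict = {}


def _interp_matrix(n_out: int, n_in: int) -> np.ndarray:
    """1-D bilinear resampling matrix, half-pixel-centre convention, edge clamp."""
    key = (n_out, n_in)
    m = _INTERP_CACHE.get(key)
    if m is None:
        m = np.zeros((n_out, n_in))
        scale = n_in / n_out
        for i in range(n_out):
            src = (i + 0.5) * scale - 0.5
            i0 = int(np.floor(src))
            f = src - i0
            lo = min(max(i0, 0), n_in - 1)
            hi = min(max(i0 + 1, 0), n_in - 1)
            m[i, lo] += 1.0 - f
            m[i, hi] += f
        _INTERP_CACHE[key] = m
    return m


def resize_bilinear(x: Tensor, out_h: int, out_w: int) -> Tensor:
    """Bilinear resize of an NCHW tensor to (out_h, out_w); exact linear map."""
    n, c, h, w = x.data.shape
    if (h, w) == (out_h, out_w):
        return x
    mh = _interp_matrix(out_h, h).astype(x.data.dtype)
    mw = _interp_matrix(out_w, w).astype(x.data.dtype)
    out_data = mh @ x.data @ mw.T

    def backward(go):
        if x.requires_grad:
            x._accum(mh.T @ go @ mw)

    return Tensor._result(out_data, (x,), backward)


_PAD_CACHE: dict = {}


def _edge_pad_matrix(n: int, p: int) -> np.ndarray:
    """0/1 selection matrix realising 1-D replicate (edge) padding."""
    key = (n, p)
    m = _PAD_CACHE.get(key)
    if m is None:
        idx = np.clip(np.arange(-p, n + p), 0, n - 1)
        m = np.zeros((n + 2 * p, n))
        m[np.arange(n + 2 * p), idx] = 1.0
        _PAD_CACHE[key] = m
    return m


def pad_replicate(x: Tensor, p: int) -> Tensor:
    """Replicate-pad the last two axes of an NCHW tensor by ``p`` pixels."""
    if p == 0:
        return x
    n, c, h, w = x.data.shape
    mh = _edge_pad_matrix(h, p).astype(x.data.dtype)
    mw = _edge_pad_matrix(w, p).astype(x.data.dtype)
    out_data = mh @ x.data @ mw.T

    def backward(go):
        if x.requires_grad:
            x._accum(mh.T @ go @ mw)

    return Tensor._result(out_data, (x,), backward)


def zero_insert2x(x: Tensor) -> Tensor:
    """Insert zeros between pixels (stride-2 dilation) — transposed-conv stage."""
    n, c, h, w = x.data.shape
    out_data = np.zeros((n, c, 2 * h, 2 * w), dtype=x.data.dtype)
    out_data[:, :, ::2, ::2] = x.data

    def backward(go):
        if x.requires_grad:
            x._accum(go[:, :, ::2, ::2])

    return Tensor._result(out_data, (x,), backward)
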