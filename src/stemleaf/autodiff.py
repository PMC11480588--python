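"""Minimal reverse-mode automatic differentiation over numpy arrays.

The segmentation network is small enough to train on a CPU, so rather than
depending on a deep-learning framework the package carries its own tape:
a :class:`Tensor` wraps an ndarray, records the backward closure of the op
that produced it, and ``backward()`` walks the tape in reverse topological
order. Only the operations the network needs are implemented; each backward
rule is unit-tested against central finite differences.
"""

from __future__ import annotations

from typing import Callable, Optional, Sequence, Union

import numpy as np

ArrayLike = Union[np.ndarray, float, int]

_DTYPE = np.float64


def set_default_dtype(dtype) -> None:
    """Set the dtype new tensors are created with.

    float64 is the default; training switches to float32 for speed (the
    numerical oracles and metrics run in plain float64 numpy regardless).
    """
    global _DTYPE
    if dtype not in (np.float32, np.float64):
        raise ValueError("dtype must be float32 or float64")
    _DTYPE = dtype


def get_default_dtype():
    return _DTYPE


class default_dtype:
    """Context manager scoping :func:`set_default_dtype`."""

    def __init__(self, dtype):
        self.dtype = dtype

    def __enter__(self):
        self.prev = _DTYPE
        set_default_dtype(self.dtype)

    def __exit__(self, *exc):
        set_default_dtype(self.prev)


_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling tape recording (inference / evaluation)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self.prev = _GRAD_ENABLED
        _GRAD_ENABLED = False

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self.prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over the axes that numpy broadcasting expanded."""
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
    """ndarray with an optional gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")
    __array_priority__ = 100  # numpy defers binary ops to Tensor

    def __init__(self, data: ArrayLike, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=_DTYPE)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad
        self._parents: tuple["Tensor", ...] = ()
        self._backward: Optional[Callable[[np.ndarray], None]] = None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _lift(x: Union["Tensor", ArrayLike]) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @staticmethod
    def _make(
        data: np.ndarray,
        parents: Sequence["Tensor"],
        backward: Callable[[np.ndarray], None],
    ) -> "Tensor":
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def _accum(self, grad: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.array(grad, dtype=self.data.dtype)  # owned copy
        else:
            self.grad += grad

    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        """Backpropagate from this tensor (default seed: ones)."""
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; deep tapes overflow recursion limits
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accum(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        a, b = self, Tensor._lift(other)
        data = a.data + b.data

        def bw(g):
            a._accum(_unbroadcast(g, a.shape))
            b._accum(_unbroadcast(g, b.shape))

        return Tensor._make(data, (a, b), bw)

    __radd__ = __add__

    def __neg__(self):
        a = self
        return Tensor._make(-a.data, (a,), lambda g: a._accum(-g))

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        a, b = self, Tensor._lift(other)
        data = a.data * b.data

        def bw(g):
            a._accum(_unbroadcast(g * b.data, a.shape))
            b._accum(_unbroadcast(g * a.data, b.shape))

        return Tensor._make(data, (a, b), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        a, b = self, Tensor._lift(other)
        data = a.data / b.data

        def bw(g):
            a._accum(_unbroadcast(g / b.data, a.shape))
            b._accum(_unbroadcast(-g * a.data / (b.data**2), b.shape))

        return Tensor._make(data, (a, b), bw)

    def __rtruediv__(self, other):
        return Tensor._lift(other) / self

    def __pow__(self, p: float):
        a = self
        data = a.data**p
        return Tensor._make(data, (a,), lambda g: a._accum(g * p * a.data ** (p - 1)))

    def __matmul__(self, other):
        a, b = self, Tensor._lift(other)
        data = a.data @ b.data

        def bw(g):
            ga = g @ np.swapaxes(b.data, -1, -2)
            gb = np.swapaxes(a.data, -1, -2) @ g
            a._accum(_unbroadcast(ga, a.shape))
            b._accum(_unbroadcast(gb, b.shape))

        return Tensor._make(data, (a, b), bw)

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        old = a.shape
        return Tensor._make(a.data.reshape(shape), (a,), lambda g: a._accum(g.reshape(old)))

    def transpose(self, axes: Sequence[int]):
        a = self
        inv = np.argsort(axes)
        return Tensor._make(
            a.data.transpose(axes), (a,), lambda g: a._accum(g.transpose(inv))
        )

    def swapaxes(self, ax1: int, ax2: int):
        a = self
        return Tensor._make(
            np.swapaxes(a.data, ax1, ax2), (a,), lambda g: a._accum(np.swapaxes(g, ax1, ax2))
        )

    def take(self, indices: np.ndarray, axis: int = 0):
        """Gather along ``axis`` with an integer index array (repeats allowed)."""
        a = self
        indices = np.asarray(indices, dtype=np.int64)
        data = np.take(a.data, indices, axis=axis)

        def bw(g):
            if axis == 0:
                # scatter-add via a sparse selection matrix: much faster than
                # np.add.at for the large neighbor gathers of the network
                from scipy import sparse

                flat_idx = indices.reshape(-1)
                g2 = np.ascontiguousarray(g).reshape(flat_idx.size, -1)
                sel = sparse.csr_matrix(
                    (
                        np.ones(flat_idx.size, dtype=g2.dtype),
                        flat_idx,
                        np.arange(flat_idx.size + 1),
                    ),
                    shape=(flat_idx.size, a.shape[0]),
                )
                a._accum((sel.T @ g2).reshape(a.shape))
            else:
                ga = np.zeros_like(a.data)
                np.add.at(ga, (slice(None),) * axis + (indices,), g)
                a._accum(ga)

        return Tensor._make(data, (a,), bw)

    def sum(self, axis=None, keepdims: bool = False):
        a = self
        data = a.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            if axis is None:
                a._accum(np.broadcast_to(g, a.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            a._accum(np.broadcast_to(g, a.shape).copy())

        return Tensor._make(data, (a,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / n

    def max(self, axis: int, keepdims: bool = False):
        a = self
        data = a.data.max(axis=axis, keepdims=keepdims)
        argmax = np.expand_dims(a.data.argmax(axis=axis), axis)

        def bw(g):
            if not keepdims:
                g = np.expand_dims(g, axis)
            ga = np.zeros_like(a.data)
            np.put_along_axis(ga, argmax, np.take_along_axis(ga, argmax, axis) + g, axis)
            a._accum(ga)

        return Tensor._make(data, (a,), bw)

    # -- elementwise nonlinearities -------------------------------------------
    def exp(self):
        a = self
        data = np.exp(a.data)
        return Tensor._make(data, (a,), lambda g: a._accum(g * data))

    def log(self):
        a = self
        return Tensor._make(np.log(a.data), (a,), lambda g: a._accum(g / a.data))

    def sqrt(self):
        a = self
        data = np.sqrt(a.data)
        return Tensor._make(data, (a,), lambda g: a._accum(g * 0.5 / data))

    def tanh(self):
        a = self
        data = np.tanh(a.data)
        return Tensor._make(data, (a,), lambda g: a._accum(g * (1.0 - data**2)))

    def sigmoid(self):
        a = self
        data = 1.0 / (1.0 + np.exp(-a.data))
        return Tensor._make(data, (a,), lambda g: a._accum(g * data * (1.0 - data)))

    def relu(self):
        a = self
        mask = a.data > 0
        return Tensor._make(a.data * mask, (a,), lambda g: a._accum(g * mask))

    def leaky_relu(self, slope: float = 0.2):
        a = self
        factor = np.where(a.data > 0, 1.0, slope)
        return Tensor._make(a.data * factor, (a,), lambda g: a._accum(g * factor))

    def clip_min(self, lo: float):
        a = self
        mask = a.data > lo
        data = np.maximum(a.data, lo)
        return Tensor._make(data, (a,), lambda g: a._accum(g * mask))

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


# -- free functions ------------------------------------------------------------


def concatenate(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accum(piece)

    return Tensor._make(data, tensors, bw)


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    data = np.stack([t.data for t in tensors], axis=axis)

    def bw(g):
        for i, t in enumerate(tensors):
            t._accum(np.take(g, i, axis=axis))

    return Tensor._make(data, tensors, bw)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax (max-shifted), differentiable."""
    shifted = x - Tensor(x.data.max(axis=axis, keepdims=True))
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x - Tensor(x.data.max(axis=axis, keepdims=True))
    return shifted - shifted.exp().sum(axis=axis, keepdims=True).log()


def attention_core(
    q: Tensor, k: Tensor, v: Tensor, key_mask: Optional[np.ndarray] = None
) -> Tensor:
    """Fused scaled-dot-product attention with a single-query per row.

    q: (B, H, dh); k, v: (B, L, H, dh); key_mask: (B, L) with True = attend.
    Returns (B, H, dh). Fusing score, softmax and weighted sum into one tape
    node keeps the training loop's memory traffic low; the backward formulas
    are the standard softmax-attention gradients.
    """
    q, k, v = Tensor._lift(q), Tensor._lift(k), Tensor._lift(v)
    dh = q.shape[-1]
    scale = 1.0 / np.sqrt(dh)
    s = np.einsum("bhd,blhd->blh", q.data, k.data) * scale
    if key_mask is not None:
        s = s + np.where(key_mask, 0.0, -1e9)[:, :, None]
    s -= s.max(axis=1, keepdims=True)
    w = np.exp(s)
    w /= w.sum(axis=1, keepdims=True)  # (B, L, H)
    out = np.einsum("blh,blhd->bhd", w, v.data)

    def bw(g):
        gv = np.einsum("blh,bhd->blhd", w, g)
        dw = np.einsum("bhd,blhd->blh", g, v.data)
        ds = w * (dw - np.einsum("blh,blh->bh", w, dw)[:, None, :])
        gq = np.einsum("blh,blhd->bhd", ds, k.data) * scale
        gk = np.einsum("blh,bhd->blhd", ds, q.data) * scale
        q._accum(gq)
        k._accum(gk)
        v._accum(gv)

    return Tensor._make(out, (q, k, v), bw)


def dot_last(a: Tensor, const_b: np.ndarray) -> Tensor:
    """Inner product over the trailing axis with a constant, broadcast on b.

    a: (..., M, D) tensor; const_b: (..., 1, D) ndarray -> (..., M). Fused so
    the (..., M, D) product is never materialized twice per pass.
    """
    a = Tensor._lift(a)
    out = np.einsum("...md,...d->...m", a.data, const_b[..., 0, :])

    def bw(g):
        a._accum(g[..., None] * const_b)

    return Tensor._make(out, (a,), bw)


def softmax_pool(h: Tensor, axis: int = 1) -> Tensor:
    """Fused attention pooling: out = sum_k softmax_k(h) * h along ``axis``.

    The gradient is w_j * (1 + h_j - out) * g (softmax-weighted-self-sum
    derivative), fused into one tape node.
    """
    h = Tensor._lift(h)
    s = h.data - h.data.max(axis=axis, keepdims=True)
    w = np.exp(s)
    w /= w.sum(axis=axis, keepdims=True)
    out = (w * h.data).sum(axis=axis)

    def bw(g):
        ge = np.expand_dims(g, axis)
        oe = np.expand_dims(out, axis)
        h._accum(ge * w * (1.0 + h.data - oe))

    return Tensor._make(out, (h,), bw)


def layer_norm(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    """LayerNorm over the last axis with learnable gain/bias (fused node)."""
    x, gain, bias = Tensor._lift(x), Tensor._lift(gain), Tensor._lift(bias)
    mu = x.data.mean(axis=-1, keepdims=True)
    xc = x.data - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out = gain.data * xhat + bias.data

    def bw(g):
        m = x.shape[-1]
        lead = tuple(range(g.ndim - 1))
        gain._accum((g * xhat).sum(axis=lead))
        bias._accum(g.sum(axis=lead))
        gx = g * gain.data
        # standard layernorm input gradient
        x._accum(
            inv * (gx - gx.mean(axis=-1, keepdims=True) - xhat * (gx * xhat).mean(axis=-1, keepdims=True))
        )

    return Tensor._make(out, (x, gain, bias), bw)
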