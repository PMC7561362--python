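"""Minimal reverse-mode automatic differentiation on NumPy arrays.

This is the numerical substrate for the package's neural layers: a
:class:`Tensor` wraps an ``ndarray`` and records enough of the computation
graph to backpropagate gradients into parameters.  Only the operations the
model architectures need are provided (broadcast arithmetic, matmul,
pointwise nonlinearities, reductions, reshaping, concatenation, slicing, a
full-height 1-D convolution and a step-gather used by the dynamic
bidirectional LSTM).

Design notes
------------
* float64 throughout; determinism matters more here than raw speed.
* Inputs (feature matrices) are constants — only parameters carry
  ``requires_grad`` — so the graph stays small.
* ``backward`` performs a single topological sweep; gradients accumulate
  into ``.grad`` as plain ndarrays.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "stack",
    "sigmoid",
    "tanh",
    "relu",
    "exp",
    "log",
    "softmax",
    "conv1d_full_height",
    "gather_steps",
]


def _sum_to_shape(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Undo NumPy broadcasting: reduce ``grad`` back to ``shape``."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An ndarray node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self.grad = None
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # -- graph plumbing ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64, copy=True)
            if self.grad.shape != self.data.shape:  # scalar broadcast
                self.grad = np.broadcast_to(self.grad, self.data.shape).copy()
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        order = _toposort(self)  # iterative: LSTM graphs exceed recursion depth
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in order:
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_sum_to_shape(g, self.data.shape))
            if other.requires_grad:
                other._accum(_sum_to_shape(g, other.data.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_sum_to_shape(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_sum_to_shape(g * self.data, other.data.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data / other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_sum_to_shape(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(
                    _sum_to_shape(-g * self.data / other.data**2, other.data.shape)
                )

        out._backward = bwd
        return out

    def __pow__(self, p: float):
        out = Tensor(self.data**p, parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1))

        out._backward = bwd
        return out

    def __matmul__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        a, b = self.data, other.data

        def bwd(g):
            if self.requires_grad:
                if b.ndim == 1:  # out = a @ v : (..., D) @ (D,) -> (...)
                    ga = g[..., None] * b
                else:
                    ga = g @ np.swapaxes(b, -1, -2)
                self._accum(_sum_to_shape(ga, a.shape))
            if other.requires_grad:
                if b.ndim == 1:
                    gb = (a * g[..., None]).reshape(-1, b.shape[0]).sum(axis=0)
                elif a.ndim == 1:
                    gb = np.outer(a, g)
                else:
                    gb = np.swapaxes(a, -1, -2) @ g
                other._accum(_sum_to_shape(gb, b.shape))

        out._backward = bwd
        return out

    # -- reductions & reshaping -------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def bwd(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.data.shape).copy())

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        elif isinstance(axis, tuple):
            n = int(np.prod([self.data.shape[a] for a in axis]))
        else:
            n = self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int):
        """Maximum along ``axis``; backward routes gradient to the argmax."""
        idx = np.argmax(self.data, axis=axis)
        out = Tensor(np.max(self.data, axis=axis), parents=(self,))

        def bwd(g):
            if not self.requires_grad:
                return
            grad = np.zeros_like(self.data)
            np.put_along_axis(
                grad, np.expand_dims(idx, axis), np.expand_dims(g, axis), axis
            )
            self._accum(grad)

        out._backward = bwd
        return out

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), parents=(self,))
        out._backward = (
            lambda g: self.requires_grad and self._accum(g.reshape(self.data.shape))
        )
        return out

    def swapaxes(self, a: int, b: int):
        out = Tensor(np.swapaxes(self.data, a, b), parents=(self,))
        out._backward = (
            lambda g: self.requires_grad and self._accum(np.swapaxes(g, a, b))
        )
        return out

    def __getitem__(self, key):
        """Basic (slice/int) indexing only — views, no duplicate positions."""
        out = Tensor(self.data[key], parents=(self,))

        def bwd(g):
            if not self.requires_grad:
                return
            grad = np.zeros_like(self.data)
            grad[key] += g
            self._accum(grad)

        out._backward = bwd
        return out

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _toposort(root: Tensor) -> list[Tensor]:
    order: list[Tensor] = []
    state: dict[int, int] = {}
    stack: list[tuple[Tensor, bool]] = [(root, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            order.append(node)
            continue
        if state.get(id(node)):
            continue
        state[id(node)] = 1
        stack.append((node, True))
        for p in node._parents:
            if not state.get(id(p)):
                stack.append((p, False))
    return order[::-1]


# -- pointwise nonlinearities ---------------------------------------------

def exp(x: Tensor) -> Tensor:
    out = Tensor(np.exp(x.data), parents=(x,))
    out._backward = lambda g: x.requires_grad and x._accum(g * out.data)
    return out


def log(x: Tensor) -> Tensor:
    out = Tensor(np.log(x.data), parents=(x,))
    out._backward = lambda g: x.requires_grad and x._accum(g / x.data)
    return out


def tanh(x: Tensor) -> Tensor:
    out = Tensor(np.tanh(x.data), parents=(x,))
    out._backward = lambda g: x.requires_grad and x._accum(g * (1.0 - out.data**2))
    return out


def sigmoid(x: Tensor) -> Tensor:
    out = Tensor(1.0 / (1.0 + np.exp(-x.data)), parents=(x,))
    out._backward = (
        lambda g: x.requires_grad and x._accum(g * out.data * (1.0 - out.data))
    )
    return out


def relu(x: Tensor) -> Tensor:
    out = Tensor(np.maximum(x.data, 0.0), parents=(x,))
    out._backward = lambda g: x.requires_grad and x._accum(g * (x.data > 0))
    return out


def softmax(x: Tensor, axis: int = -1, mask: np.ndarray | None = None) -> Tensor:
    """Softmax along ``axis``.

    ``mask`` (same shape, boolean) marks valid entries; invalid positions get
    probability exactly 0.  Rows with no valid entry come out all-zero rather
    than NaN — callers that need a fallback handle it explicitly.
    """
    z = x.data
    if mask is not None:
        # additive -inf penalty: exp underflows to exactly 0 on masked
        # entries even when their raw values are arbitrarily large
        x = x + Tensor(np.where(mask, 0.0, -np.inf))
        z = x.data
    with np.errstate(invalid="ignore"):
        zmax = np.max(z, axis=axis, keepdims=True)
        zmax = np.where(np.isfinite(zmax), zmax, 0.0)
        shifted = x - Tensor(zmax)
        e = exp(shifted)
    denom = e.sum(axis=axis, keepdims=True)
    # avoid 0/0 for fully-masked rows by clamping their denominator to 1
    denom = denom + Tensor((denom.data == 0.0).astype(np.float64))
    return e / denom


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accum(piece)

    out._backward = bwd
    return out


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out = Tensor(np.stack([t.data for t in tensors], axis=axis), parents=tuple(tensors))

    def bwd(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accum(np.take(g, i, axis=axis))

    out._backward = bwd
    return out


def conv1d_full_height(x: Tensor, weight: Tensor, bias: Tensor) -> Tensor:
    """Valid cross-correlation of full-height kernels over the bin axis.

    ``x``: (B, C, T); ``weight``: (K, C, W); ``bias``: (K,).
    Output: (B, K, T - W + 1).  Kernels span all C channels, so each kernel
    produces a single output row (e.g. a 7x7 kernel on a 7x40 matrix yields
    a length-34 vector).
    """
    B, C, T = x.data.shape
    K, C2, W = weight.data.shape
    if C2 != C:
        raise ValueError(f"kernel height {C2} != input channels {C}")
    patches = np.lib.stride_tricks.sliding_window_view(x.data, W, axis=2)  # (B,C,L,W)
    out_data = np.einsum("bclw,kcw->bkl", patches, weight.data) + bias.data[None, :, None]
    out = Tensor(out_data, parents=(x, weight, bias))

    def bwd(g):
        if weight.requires_grad:
            weight._accum(np.einsum("bclw,bkl->kcw", patches, g))
        if bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2)))
        if x.requires_grad:
            gx = np.zeros_like(x.data)
            contrib = np.einsum("bkl,kcw->bclw", g, weight.data)
            L = T - W + 1
            for w in range(W):
                gx[:, :, w : w + L] += contrib[:, :, :, w]
            x._accum(gx)

    out._backward = bwd
    return out


def gather_steps(x: Tensor, idx: np.ndarray) -> Tensor:
    """Per-sample reindexing of time steps: out[b, t] = x[b, idx[b, t]].

    ``x``: (B, T, D); ``idx``: (B, T) int.  Used to re-align the reversed
    direction of a dynamic bidirectional LSTM run on padded batches.
    """
    B, T, D = x.data.shape
    rows = np.arange(B)[:, None]
    out = Tensor(x.data[rows, idx], parents=(x,))

    def bwd(g):
        if not x.requires_grad:
            return
        grad = np.zeros_like(x.data)
        np.add.at(grad, (rows, idx), g)
        x._accum(grad)

    out._backward = bwd
    return out
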