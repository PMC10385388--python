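"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Implements exactly the operator set the spectral networks in this package
need: broadcast-aware arithmetic, batched ``matmul``, the usual pointwise
nonlinearities, axis reductions, reshaping/slicing/concatenation, a 1-D
convolution and max-pooling for the convolutional baseline, plus stable
softmax / log-sum-exp helpers. Gradients are accumulated by topological
traversal of the recorded graph, as in every define-by-run framework.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "softmax",
    "logsumexp",
    "cross_entropy",
    "relu",
    "sigmoid",
    "conv1d",
    "max_pool1d",
]


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
    return grad.reshape(shape)


class Tensor:
    """An n-d array node in a dynamically recorded computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------

    @classmethod
    def _from_op(cls, data, parents, backward):
        out = cls(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic -----------------------------------------------------------

    def __add__(self, other):
        other = as_tensor(other)
        out_data = self.data + other.data

        def backward(g):
            return _unbroadcast(g, self.shape), _unbroadcast(g, other.shape)

        return Tensor._from_op(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return Tensor._from_op(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out_data = self.data * other.data

        def backward(g):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        return Tensor._from_op(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out_data = self.data / other.data

        def backward(g):
            return (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            )

        return Tensor._from_op(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        out_data = self.data**exponent

        def backward(g):
            return (g * exponent * self.data ** (exponent - 1),)

        return Tensor._from_op(out_data, (self,), backward)

    def __matmul__(self, other):
        other = as_tensor(other)
        out_data = self.data @ other.data
        a, b = self, other

        def backward(g):
            if b.data.ndim == 1:
                ga = np.outer(g, b.data) if a.data.ndim > 1 else g * b.data
                gb = a.data.T @ g if a.data.ndim > 1 else g * a.data
            else:
                ga = g @ np.swapaxes(b.data, -1, -2)
                gb = np.swapaxes(a.data, -1, -2) @ g
            return _unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape)

        return Tensor._from_op(out_data, (self, other), backward)

    # -- pointwise nonlinearities ---------------------------------------------

    def exp(self):
        out_data = np.exp(self.data)
        return Tensor._from_op(out_data, (self,), lambda g: (g * out_data,))

    def log(self):
        return Tensor._from_op(np.log(self.data), (self,), lambda g: (g / self.data,))

    def sqrt(self):
        return self**0.5

    def tanh(self):
        out_data = np.tanh(self.data)
        return Tensor._from_op(out_data, (self,), lambda g: (g * (1.0 - out_data**2),))

    def relu(self):
        mask = self.data > 0
        return Tensor._from_op(self.data * mask, (self,), lambda g: (g * mask,))

    def sigmoid(self):
        out_data = 0.5 * (1.0 + np.tanh(0.5 * self.data))
        return Tensor._from_op(
            out_data, (self,), lambda g: (g * out_data * (1.0 - out_data),)
        )

    # -- reductions -----------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        shape, nd = self.shape, self.ndim

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                axes = axis if isinstance(axis, tuple) else (axis,)
                g = np.expand_dims(g, tuple(a % nd for a in axes))
            return (np.broadcast_to(g, shape).copy(),)

        return Tensor._from_op(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def max(self, axis: int, keepdims: bool = False):
        out_data = self.data.max(axis=axis, keepdims=keepdims)
        argmax = np.expand_dims(self.data.argmax(axis=axis), axis)

        def backward(g):
            g = np.asarray(g)
            if not keepdims:
                g = np.expand_dims(g, axis)
            full = np.zeros_like(self.data)
            np.put_along_axis(full, argmax, g, axis)
            return (full,)

        return Tensor._from_op(out_data, (self,), backward)

    # -- shape manipulation ---------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape
        return Tensor._from_op(
            self.data.reshape(shape), (self,), lambda g: (g.reshape(old),)
        )

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inverse = np.argsort(axes)
        return Tensor._from_op(
            self.data.transpose(axes), (self,), lambda g: (g.transpose(inverse),)
        )

    def swapaxes(self, a: int, b: int):
        return Tensor._from_op(
            np.swapaxes(self.data, a, b), (self,), lambda g: (np.swapaxes(g, a, b),)
        )

    def __getitem__(self, key):
        out_data = self.data[key]

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, key, g)
            return (full,)

        return Tensor._from_op(out_data, (self,), backward)

    # -- autodiff driver ------------------------------------------------------

    def backward(self, grad=None):
        if grad is None:
            if self.size != 1:
                raise ValueError("backward() without a gradient needs a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; recursion depth is unbounded for RNN graphs
            node, expanded = stack.pop()
            if expanded:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                node.grad = g if node.grad is None else node.grad + g
                continue
            for parent, pg in zip(node._parents, node._backward(g)):
                if not parent.requires_grad:
                    continue
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg
        # leaves with recorded ops but requires_grad (non-leaf .grad unused)
        if self._backward is None and self.requires_grad and id(self) in grads:
            self.grad = grads[id(self)]

    def zero_grad(self):
        self.grad = None


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._from_op(out_data, tuple(tensors), backward)


def relu(x) -> Tensor:
    return as_tensor(x).relu()


def sigmoid(x) -> Tensor:
    return as_tensor(x).sigmoid()


def softmax(x, axis: int = -1) -> Tensor:
    """Numerically stable softmax; the max shift is a constant, so the
    gradient is unaffected."""
    x = as_tensor(x)
    shifted = x - Tensor(x.data.max(axis=axis, keepdims=True))
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def logsumexp(x, axis: int = -1) -> Tensor:
    x = as_tensor(x)
    m = x.data.max(axis=axis, keepdims=True)
    e = (x - Tensor(m)).exp()
    return e.sum(axis=axis).log() + Tensor(np.squeeze(m, axis=axis))


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean categorical cross-entropy from raw logits and integer labels."""
    labels = np.asarray(labels)
    onehot = np.zeros(logits.shape)
    onehot[np.arange(labels.size), labels] = 1.0
    picked = (logits * Tensor(onehot)).sum(axis=-1)
    return (logsumexp(logits, axis=-1) - picked).mean()


def conv1d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Valid-padding 1-D convolution (cross-correlation).

    x: (B, S, C_in); w: (K, C_in, C_out); b: (C_out,) → (B, S-K+1, C_out).
    """
    x, w, b = as_tensor(x), as_tensor(w), as_tensor(b)
    K = w.shape[0]
    windows = np.lib.stride_tricks.sliding_window_view(x.data, K, axis=1)
    # windows: (B, S-K+1, C_in, K) → einsum with w (K, C_in, C_out)
    out_data = np.einsum("bsck,kco->bso", windows, w.data) + b.data

    def backward(g):
        gw = np.einsum("bsck,bso->kco", windows, g)
        gb = g.sum(axis=(0, 1))
        gx = np.zeros_like(x.data)
        for k in range(K):  # K is small (filter width)
            gx[:, k : k + g.shape[1], :] += np.einsum("bso,co->bsc", g, w.data[k])
        return gx, gw, gb

    return Tensor._from_op(out_data, (x, w, b), backward)


def max_pool1d(x: Tensor, pool: int = 2) -> Tensor:
    """Non-overlapping max pooling along the sequence axis; trailing
    remainder steps are dropped."""
    x = as_tensor(x)
    B, S, C = x.shape
    s_out = S // pool
    trimmed = x[:, : s_out * pool, :]
    return trimmed.reshape(B, s_out, pool, C).max(axis=2)
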