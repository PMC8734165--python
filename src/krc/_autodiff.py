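"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations needed by the reading-comprehension model:
broadcast arithmetic, matrix products, ReLU, (log-)softmax, layer
normalisation, reductions, reshaping, concatenation and row gathering.
Gradients are accumulated into ``Tensor.grad`` by :meth:`Tensor.backward`,
which walks the tape in reverse topological order.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "gather_rows", "layer_norm"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array with an optional gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple = (), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad or any(
            p.requires_grad for p in parents)
        self.grad = None
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    # -- graph traversal ---------------------------------------------------

    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
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
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if not node._parents:
                node.grad = g if node.grad is None else node.grad + g
                continue
            for parent, pg in node._backward(g):
                if not parent.requires_grad:
                    continue
                key = id(parent)
                if key in grads:
                    grads[key] = grads[key] + pg
                else:
                    grads[key] = pg

    # -- arithmetic --------------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))

    def __add__(self, other):
        other = self._lift(other)
        out_data = self.data + other.data
        def bwd(g):
            return ((self, _unbroadcast(g, self.shape)),
                    (other, _unbroadcast(g, other.shape)))
        return Tensor(out_data, parents=(self, other), backward=bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            return ((self, -g),)
        return Tensor(-self.data, parents=(self,), backward=bwd)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out_data = self.data * other.data
        def bwd(g):
            return ((self, _unbroadcast(g * other.data, self.shape)),
                    (other, _unbroadcast(g * self.data, other.shape)))
        return Tensor(out_data, parents=(self, other), backward=bwd)

    __rmul__ = __mul__

    def __truediv__(self, scalar):
        if isinstance(scalar, Tensor):
            raise TypeError("division only supported by python scalars")
        return self * (1.0 / scalar)

    def __matmul__(self, other):
        other = self._lift(other)
        out_data = self.data @ other.data
        def bwd(g):
            ga = g @ np.swapaxes(other.data, -1, -2)
            gb = np.swapaxes(self.data, -1, -2) @ g
            return ((self, _unbroadcast(ga, self.shape)),
                    (other, _unbroadcast(gb, other.shape)))
        return Tensor(out_data, parents=(self, other), backward=bwd)

    # -- nonlinearities ----------------------------------------------------

    def relu(self):
        mask = self.data > 0
        def bwd(g):
            return ((self, g * mask),)
        return Tensor(self.data * mask, parents=(self,), backward=bwd)

    def log(self):
        def bwd(g):
            return ((self, g / self.data),)
        return Tensor(np.log(self.data), parents=(self,), backward=bwd)

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)
        def bwd(g):
            dot = (g * s).sum(axis=axis, keepdims=True)
            return ((self, s * (g - dot)),)
        return Tensor(s, parents=(self,), backward=bwd)

    def log_softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
        out = z - lse
        sm = np.exp(out)
        def bwd(g):
            return ((self, g - sm * g.sum(axis=axis, keepdims=True)),)
        return Tensor(out, parents=(self,), backward=bwd)

    # -- reductions & shaping ----------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        def bwd(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return ((self, np.broadcast_to(g, self.shape).copy()),)
        return Tensor(out_data, parents=(self,), backward=bwd)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / n

    def reshape(self, *shape):
        orig = self.shape
        def bwd(g):
            return ((self, g.reshape(orig)),)
        return Tensor(self.data.reshape(*shape), parents=(self,), backward=bwd)

    def transpose(self, *axes):
        axes = axes or tuple(reversed(range(self.ndim)))
        inv = np.argsort(axes)
        def bwd(g):
            return ((self, g.transpose(inv)),)
        return Tensor(self.data.transpose(axes), parents=(self,), backward=bwd)

    def __getitem__(self, idx):
        out_data = self.data[idx]
        def bwd(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return ((self, full),)
        return Tensor(out_data, parents=(self,), backward=bwd)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)
    def bwd(g):
        grads = []
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            grads.append((t, g[tuple(sl)]))
        return tuple(grads)
    return Tensor(out_data, parents=tuple(tensors), backward=bwd)


def gather_rows(table: Tensor, indices: np.ndarray) -> Tensor:
    """Row lookup ``table[indices]`` (embedding gather)."""
    indices = np.asarray(indices)
    out_data = table.data[indices]
    def bwd(g):
        full = np.zeros_like(table.data)
        np.add.at(full, indices, g)
        return ((table, full),)
    return Tensor(out_data, parents=(table,), backward=bwd)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor,
               eps: float = 1e-5) -> Tensor:
    """Normalise the last axis of ``x`` and apply an affine transform."""
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out_data = xhat * gamma.data + beta.data
    def bwd(g):
        gg = _unbroadcast(g * xhat, gamma.shape)
        gb = _unbroadcast(g, beta.shape)
        gx_hat = g * gamma.data
        gx = inv * (gx_hat
                    - gx_hat.mean(axis=-1, keepdims=True)
                    - xhat * (gx_hat * xhat).mean(axis=-1, keepdims=True))
        return ((x, gx), (gamma, gg), (beta, gb))
    return Tensor(out_data, parents=(x, gamma, beta), backward=bwd)
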