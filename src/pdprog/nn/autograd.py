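"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Supports exactly the operations the package's networks need: broadcasting
arithmetic, matmul (including batched), elementwise nonlinearities,
reductions, reshaping/transposition, concatenation, basic indexing and
row-gather (embedding lookup).  Gradients are accumulated into ``.grad``
arrays by :meth:`Tensor.backward` in reverse topological order.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum away prepended axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic ----------------------------------------------------------
    @staticmethod
    def _coerce(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._coerce(other)
        out_data = self.data + other.data

        def backward(g):
            return (_unbroadcast(g, self.data.shape), _unbroadcast(g, other.data.shape))

        return self._make2(out_data, (self, other), backward)

    def __radd__(self, other):
        return self.__add__(other)

    def __neg__(self):
        def backward(g):
            return (-g,)
        return self._make2(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        a, b = self.data, other.data

        def backward(g):
            return (_unbroadcast(g * b, a.shape), _unbroadcast(g * a, b.shape))

        return self._make2(a * b, (self, other), backward)

    def __rmul__(self, other):
        return self.__mul__(other)

    def __truediv__(self, other):
        other = self._coerce(other)
        a, b = self.data, other.data

        def backward(g):
            return (_unbroadcast(g / b, a.shape),
                    _unbroadcast(-g * a / (b * b), b.shape))

        return self._make2(a / b, (self, other), backward)

    def __rtruediv__(self, other):
        return self._coerce(other) / self

    def __pow__(self, exponent: float):
        a = self.data

        def backward(g):
            return (g * exponent * np.power(a, exponent - 1),)

        return self._make2(np.power(a, exponent), (self,), backward)

    def __matmul__(self, other):
        other = self._coerce(other)
        a, b = self.data, other.data

        def backward(g):
            ga = np.matmul(g, np.swapaxes(b, -1, -2))
            gb = np.matmul(np.swapaxes(a, -1, -2), g)
            return (_unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape))

        return self._make2(np.matmul(a, b), (self, other), backward)

    # variant of _make that records gradients for all parents (even frozen
    # ones get skipped at accumulation time)
    def _make2(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    # -- nonlinearities ------------------------------------------------------
    def exp(self):
        e = np.exp(self.data)

        def backward(g):
            return (g * e,)

        return self._make2(e, (self,), backward)

    def log(self):
        a = self.data

        def backward(g):
            return (g / a,)

        return self._make2(np.log(a), (self,), backward)

    def tanh(self):
        t = np.tanh(self.data)

        def backward(g):
            return (g * (1 - t * t),)

        return self._make2(t, (self,), backward)

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            return (g * s * (1 - s),)

        return self._make2(s, (self,), backward)

    def relu(self):
        m = self.data > 0

        def backward(g):
            return (g * m,)

        return self._make2(self.data * m, (self,), backward)

    def sqrt(self):
        r = np.sqrt(self.data)

        def backward(g):
            return (g * 0.5 / r,)

        return self._make2(r, (self,), backward)

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        a = self.data

        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, a.shape).copy(),)
            g2 = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(g2, a.shape).copy(),)

        return self._make2(a.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims=False):
        a = self.data
        n = a.size if axis is None else a.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape ops -----------------------------------------------------------
    def reshape(self, *shape):
        a_shape = self.data.shape

        def backward(g):
            return (g.reshape(a_shape),)

        return self._make2(self.data.reshape(*shape), (self,), backward)

    def swapaxes(self, ax1, ax2):
        def backward(g):
            return (np.swapaxes(g, ax1, ax2),)

        return self._make2(np.swapaxes(self.data, ax1, ax2), (self,), backward)

    def __getitem__(self, key):
        a = self.data

        def backward(g):
            full = np.zeros_like(a)
            np.add.at(full, key, g)
            return (full,)

        return self._make2(a[key], (self,), backward)

    def take_rows(self, indices: np.ndarray):
        """Gather rows of a 2-D tensor: embedding lookup.

        ``indices`` may have any shape; output shape = indices.shape + (D,).
        """
        idx = np.asarray(indices)
        a = self.data

        def backward(g):
            full = np.zeros_like(a)
            np.add.at(full, idx.reshape(-1),
                      g.reshape(-1, a.shape[1]))
            return (full,)

        return self._make2(a[idx], (self,), backward)

    # -- graph traversal -----------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in visited:
                    stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad and node._backward is None:
                # leaf parameter
                node.grad = g if node.grad is None else node.grad + g
            if node._backward is None:
                continue
            parent_grads = node._backward(g)
            for p, pg in zip(node._parents, parent_grads):
                if not p.requires_grad:
                    continue
                if id(p) in grads:
                    grads[id(p)] = grads[id(p)] + pg
                else:
                    grads[id(p)] = pg


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    out = Tensor(np.concatenate(datas, axis=axis))
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)
        out._backward = backward
    return out


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    datas = [t.data for t in tensors]

    def backward(g):
        return tuple(np.moveaxis(g, axis, 0))

    out = Tensor(np.stack(datas, axis=axis))
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)
        out._backward = backward
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x + Tensor(-x.data.max(axis=axis, keepdims=True))
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x + Tensor(-x.data.max(axis=axis, keepdims=True))
    return shifted - shifted.exp().sum(axis=axis, keepdims=True).log()
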