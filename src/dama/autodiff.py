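"""Minimal reverse-mode automatic differentiation over NumPy arrays.

A tape-free, graph-based implementation: each :class:`Tensor` records the
operation that produced it and closures computing vector–Jacobian products
for its parents.  ``Tensor.backward()`` topologically sorts the graph and
accumulates gradients.  The op set is exactly what the gated multi-hop
attention model needs — elementwise arithmetic with broadcasting, matmul,
exp/tanh/log/sqrt/relu/elu/abs, reductions, row gathering and segment sums
(the scatter-add primitive behind sparse attention).

Gradients are checked against central finite differences in the test
suite.
"""

from __future__ import annotations

from typing import Callable, Iterable

import numpy as np

__all__ = ["Tensor", "concat", "segment_sum", "gather_rows"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """N-d array with reverse-mode gradient support."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_vjps")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._vjps: tuple[Callable[[np.ndarray], np.ndarray], ...] = ()

    # -- construction helpers ---------------------------------------------

    @staticmethod
    def _make(data: np.ndarray, parents: Iterable["Tensor"],
              vjps: Iterable[Callable]) -> "Tensor":
        parents = tuple(parents)
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = parents
            out._vjps = tuple(vjps)
        return out

    @staticmethod
    def as_tensor(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        o = Tensor.as_tensor(other)
        return Tensor._make(
            self.data + o.data, (self, o),
            (lambda g: _unbroadcast(g, self.shape),
             lambda g: _unbroadcast(g, o.shape)))

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, (self,), (lambda g: -g,))

    def __sub__(self, other):
        return self + (-Tensor.as_tensor(other))

    def __rsub__(self, other):
        return Tensor.as_tensor(other) + (-self)

    def __mul__(self, other):
        o = Tensor.as_tensor(other)
        return Tensor._make(
            self.data * o.data, (self, o),
            (lambda g: _unbroadcast(g * o.data, self.shape),
             lambda g: _unbroadcast(g * self.data, o.shape)))

    __rmul__ = __mul__

    def __truediv__(self, other):
        o = Tensor.as_tensor(other)
        return Tensor._make(
            self.data / o.data, (self, o),
            (lambda g: _unbroadcast(g / o.data, self.shape),
             lambda g: _unbroadcast(-g * self.data / o.data**2, o.shape)))

    def __rtruediv__(self, other):
        return Tensor.as_tensor(other) / self

    def __matmul__(self, other):
        o = Tensor.as_tensor(other)
        return Tensor._make(
            self.data @ o.data, (self, o),
            (lambda g: g @ np.swapaxes(o.data, -1, -2),
             lambda g: np.swapaxes(self.data, -1, -2) @ g))

    def __pow__(self, p: float):
        return Tensor._make(
            self.data**p, (self,),
            (lambda g: g * p * self.data ** (p - 1),))

    # -- elementwise nonlinearities ---------------------------------------

    def exp(self):
        out_data = np.exp(self.data)
        return Tensor._make(out_data, (self,), (lambda g: g * out_data,))

    def log(self):
        return Tensor._make(np.log(self.data), (self,), (lambda g: g / self.data,))

    def tanh(self):
        out_data = np.tanh(self.data)
        return Tensor._make(out_data, (self,), (lambda g: g * (1 - out_data**2),))

    def sqrt(self):
        out_data = np.sqrt(self.data)
        return Tensor._make(out_data, (self,), (lambda g: g * 0.5 / out_data,))

    def relu(self):
        mask = self.data > 0
        return Tensor._make(self.data * mask, (self,), (lambda g: g * mask,))

    def elu(self, alpha: float = 1.0):
        pos = self.data > 0
        out_data = np.where(pos, self.data, alpha * np.expm1(self.data))
        return Tensor._make(
            out_data, (self,),
            (lambda g: g * np.where(pos, 1.0, out_data + alpha),))

    def abs(self):
        sign = np.sign(self.data)
        return Tensor._make(np.abs(self.data), (self,), (lambda g: g * sign,))

    # -- reductions & shaping ---------------------------------------------

    def sum(self, axis=None, keepdims=False):
        def vjp(g):
            if axis is None:
                return np.broadcast_to(g, self.shape).copy()
            gg = g if keepdims else np.expand_dims(g, axis)
            return np.broadcast_to(gg, self.shape).copy()
        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), (vjp,))

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        return Tensor._make(
            self.data.reshape(*shape), (self,),
            (lambda g: g.reshape(self.shape),))

    def __getitem__(self, key):
        def vjp(g):
            out = np.zeros(self.shape)
            np.add.at(out, key, g)
            return out
        return Tensor._make(self.data[key], (self,), (vjp,))

    # -- backward ----------------------------------------------------------

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: deep graphs must not hit the recursion limit
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
            for p, vjp in zip(node._parents, node._vjps):
                if not p.requires_grad:
                    continue
                pg = vjp(g)
                if id(p) in grads:
                    grads[id(p)] = grads[id(p)] + pg
                else:
                    grads[id(p)] = pg
        # leaves reached directly (self may itself be a leaf)
        if not self._parents and self.requires_grad and self.grad is None:
            self.grad = np.asarray(grad, dtype=np.float64)


# -- free functions --------------------------------------------------------


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def make_vjp(i):
        return lambda g: np.split(g, splits, axis=axis)[i]

    return Tensor._make(
        np.concatenate(datas, axis=axis), tensors,
        tuple(make_vjp(i) for i in range(len(tensors))))


def gather_rows(x: Tensor, idx: np.ndarray) -> Tensor:
    """Rows ``x[idx]`` with scatter-add backward."""
    return x[idx]


def segment_sum(x: Tensor, seg_ids: np.ndarray, n_segments: int) -> Tensor:
    """Sum rows of ``x`` into ``n_segments`` buckets given by ``seg_ids``.

    The gradient of a bucket flows unchanged to each of its members
    (backward is a gather).
    """
    out_shape = (n_segments,) + x.data.shape[1:]
    out_data = np.zeros(out_shape)
    np.add.at(out_data, seg_ids, x.data)
    return Tensor._make(out_data, (x,), (lambda g: g[seg_ids],))
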