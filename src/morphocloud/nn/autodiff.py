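"""Minimal reverse-mode automatic differentiation on numpy arrays.

This engine provides exactly the operations the vector-neuron layers and
decoders need: broadcasting arithmetic, two-operand ``einsum``, reductions,
gather, concatenation, clip-free nonlinearities built from constant masks,
and the 3-vector cross product. Gradients are accumulated by topological
traversal of the computation graph.

Design constraints:

* every ``Tensor`` wraps a float64 ndarray; constants are wrapped lazily;
* ``einsum`` supports two operands with non-repeated subscripts per operand,
  every input label appearing in the output or the other operand — enough for
  channel-mixing linear maps and batched contractions;
* branch decisions (masks, nearest-neighbour indices, assignment problems)
  are taken on values and treated as constants, as in mainstream frameworks.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "add",
    "sub",
    "mul",
    "div",
    "neg",
    "einsum",
    "concat",
    "gather",
    "reduce_sum",
    "reduce_mean",
    "square",
    "sqrt",
    "cross",
    "leaky_relu",
    "relu",
]


class Tensor:
    """Node in the computation graph.

    Parameters
    ----------
    data:
        Array value of this node.
    parents:
        Tuple of parent ``Tensor`` objects this node was computed from.
    grad_fn:
        Callable mapping the incoming gradient to a tuple of gradients,
        one per parent (``None`` allowed for non-differentiable parents).
    requires_grad:
        Whether gradients should be accumulated into ``self.grad``.
    """

    __slots__ = ("data", "parents", "grad_fn", "requires_grad", "grad")

    def __init__(self, data, parents=(), grad_fn=None, requires_grad=False):
        self.data = np.asarray(data, dtype=np.float64)
        self.parents = tuple(parents)
        self.grad_fn = grad_fn
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in self.parents
        )
        self.grad = None

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self):
        return Tensor(self.data)

    # -- operators -------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __sub__(self, other):
        return sub(self, other)

    def __rsub__(self, other):
        return sub(other, self)

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, other)

    def __neg__(self):
        return neg(self)

    def backward(self, grad=None):
        """Backpropagate from this node.

        ``grad`` defaults to ones (scalar outputs expect shape ``()``).
        """
        if grad is None:
            grad = np.ones_like(self.data)
        # iterative topological sort to avoid recursion limits on deep graphs
        order = _toposort(self)
        grads = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in order:
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad and node.grad_fn is None and not node.parents:
                node.grad = g if node.grad is None else node.grad + g
            if node.grad_fn is None:
                continue
            parent_grads = node.grad_fn(g)
            for p, pg in zip(node.parents, parent_grads):
                if pg is None or not p.requires_grad:
                    continue
                if id(p) in grads:
                    grads[id(p)] = grads[id(p)] + pg
                else:
                    grads[id(p)] = pg


def _toposort(root):
    """Return nodes in reverse-topological (output-first) order, iteratively."""
    out, seen, stack = [], set(), [(root, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            out.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node.parents:
            if p.requires_grad and id(p) not in seen:
                stack.append((p, False))
    out.reverse()
    return out


def as_tensor(x):
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(grad, shape):
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


def add(a, b):
    a, b = as_tensor(a), as_tensor(b)
    return Tensor(
        a.data + b.data,
        (a, b),
        lambda g: (_unbroadcast(g, a.shape), _unbroadcast(g, b.shape)),
    )


def sub(a, b):
    a, b = as_tensor(a), as_tensor(b)
    return Tensor(
        a.data - b.data,
        (a, b),
        lambda g: (_unbroadcast(g, a.shape), _unbroadcast(-g, b.shape)),
    )


def neg(a):
    a = as_tensor(a)
    return Tensor(-a.data, (a,), lambda g: (-g,))


def mul(a, b):
    a, b = as_tensor(a), as_tensor(b)
    return Tensor(
        a.data * b.data,
        (a, b),
        lambda g: (
            _unbroadcast(g * b.data, a.shape),
            _unbroadcast(g * a.data, b.shape),
        ),
    )


def div(a, b):
    a, b = as_tensor(a), as_tensor(b)
    return Tensor(
        a.data / b.data,
        (a, b),
        lambda g: (
            _unbroadcast(g / b.data, a.shape),
            _unbroadcast(-g * a.data / (b.data**2), b.shape),
        ),
    )


def einsum(subscripts, a, b):
    """Two-operand einsum with gradients.

    Each operand's subscripts must be repetition-free and each input label
    must appear in the output or in the other operand.
    """
    a, b = as_tensor(a), as_tensor(b)
    inputs, out = subscripts.replace(" ", "").split("->")
    sa, sb = inputs.split(",")
    if len(set(sa)) != len(sa) or len(set(sb)) != len(sb):
        raise ValueError("repeated labels within one operand are unsupported")
    for lab in sa:
        if lab not in out and lab not in sb:
            raise ValueError(f"label {lab!r} summed within a single operand")
    for lab in sb:
        if lab not in out and lab not in sa:
            raise ValueError(f"label {lab!r} summed within a single operand")
    val = np.einsum(subscripts, a.data, b.data, optimize=True)

    def grad_fn(g):
        ga = np.einsum(f"{out},{sb}->{sa}", g, b.data, optimize=True)
        gb = np.einsum(f"{out},{sa}->{sb}", g, a.data, optimize=True)
        return ga, gb

    return Tensor(val, (a, b), grad_fn)


def concat(tensors, axis):
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def grad_fn(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor(
        np.concatenate([t.data for t in tensors], axis=axis), tensors, grad_fn
    )


def gather(a, index):
    """Index the leading axis with an integer array (``a[index]``)."""
    a = as_tensor(a)
    index = np.asarray(index)

    def grad_fn(g):
        out = np.zeros_like(a.data)
        np.add.at(out, index.reshape(-1), g.reshape((-1,) + a.shape[1:]))
        return (out,)

    return Tensor(a.data[index], (a,), grad_fn)


def reduce_sum(a, axis=None, keepdims=False):
    a = as_tensor(a)

    def grad_fn(g):
        if axis is None:
            return (np.broadcast_to(g, a.shape).copy(),)
        g2 = g if keepdims else np.expand_dims(g, axis)
        return (np.broadcast_to(g2, a.shape).copy(),)

    return Tensor(a.data.sum(axis=axis, keepdims=keepdims), (a,), grad_fn)


def reduce_mean(a, axis=None, keepdims=False):
    a = as_tensor(a)
    n = a.data.size if axis is None else a.shape[axis]
    s = reduce_sum(a, axis=axis, keepdims=keepdims)
    return mul(s, 1.0 / n)


def reshape(a, shape):
    a = as_tensor(a)
    return Tensor(
        a.data.reshape(shape), (a,), lambda g: (g.reshape(a.shape),)
    )


def tile_rows(a, n):
    """Broadcast a 1-D tensor to (n, len(a)) with summed gradients."""
    a = as_tensor(a)
    return gather(reshape(a, (1, -1)), np.zeros(n, dtype=int))


def square(a):
    a = as_tensor(a)
    return Tensor(a.data**2, (a,), lambda g: (2.0 * g * a.data,))


def sqrt(a):
    a = as_tensor(a)
    val = np.sqrt(a.data)
    return Tensor(val, (a,), lambda g: (0.5 * g / np.maximum(val, 1e-300),))


def cross(a, b):
    """Cross product along the last axis (size 3)."""
    a, b = as_tensor(a), as_tensor(b)
    val = np.cross(a.data, b.data)

    def grad_fn(g):
        ga = _unbroadcast(np.cross(b.data, g), a.shape)
        gb = _unbroadcast(np.cross(g, a.data), b.shape)
        return ga, gb

    return Tensor(val, (a, b), grad_fn)


def leaky_relu(a, alpha=0.2):
    a = as_tensor(a)
    mask = np.where(a.data >= 0, 1.0, alpha)
    return Tensor(a.data * mask, (a,), lambda g: (g * mask,))


def relu(a):
    return leaky_relu(a, alpha=0.0)


class Parameter(Tensor):
    """Leaf tensor with gradient accumulation enabled."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Adam:
    """Adam optimizer over a list of :class:`Parameter`."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
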