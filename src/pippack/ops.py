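"""A small reverse-mode automatic-differentiation engine over NumPy arrays.

The module exposes a :class:`Tensor` wrapping a float64 ndarray plus a set of
module-level functions (``sin``, ``matmul``, ``concatenate``, ...) that accept
either Tensors or plain ndarrays.  When no Tensor is involved the functions
fall through to NumPy, so geometric code written against this module runs at
native NumPy speed outside of training and becomes differentiable when handed
Tensors.  Gradients propagate by topological-order backward passes; broadcast
dimensions are summed out on the way back.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor", "is_tensor", "as_array", "add", "mul", "sub", "div", "matmul",
    "sum_", "mean_", "exp", "log", "sin", "cos", "tanh", "sqrt", "relu",
    "softplus", "concatenate", "stack", "reshape", "transpose", "broadcast_to",
    "take", "softmax", "log_softmax", "cross", "norm", "where",
]


def is_tensor(x) -> bool:
    return isinstance(x, Tensor)


def as_array(x) -> np.ndarray:
    """Underlying ndarray of a Tensor, or the input coerced to an ndarray."""
    return x.data if is_tensor(x) else np.asarray(x, dtype=np.float64)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum out broadcast axes so grad matches the original operand shape."""
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
    """A float64 array node in the autodiff graph."""

    __slots__ = ("data", "grad", "parents", "_backward", "requires_grad")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.parents = parents
        self._backward = backward
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(node):
            if id(node) in seen or not node.requires_grad:
                return
            seen.add(id(node))
            for p in node.parents:
                visit(p)
            topo.append(node)

        visit(self)
        for node in topo:
            if node.grad is None:  # keep accumulated leaf grads across calls
                node.grad = np.zeros_like(node.data)
        self.grad = self.grad + np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # -- operators ---------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return sub(self, other)

    def __rsub__(self, other):
        return sub(other, self)

    def __neg__(self):
        return mul(self, -1.0)

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(other, self)

    def __pow__(self, p):
        return power(self, p)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return take(self, idx)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    def sum(self, axis=None, keepdims=False):
        return sum_(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return mean_(self, axis=axis, keepdims=keepdims)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def _binary(x, y, fwd, bwd_x, bwd_y):
    if not (is_tensor(x) or is_tensor(y)):
        return fwd(np.asarray(x, dtype=np.float64), np.asarray(y, dtype=np.float64))
    xt = x if is_tensor(x) else Tensor(x)
    yt = y if is_tensor(y) else Tensor(y)
    out_data = fwd(xt.data, yt.data)

    def backward(g):
        if xt.requires_grad:
            xt.grad += _unbroadcast(bwd_x(g, xt.data, yt.data), xt.data.shape)
        if yt.requires_grad:
            yt.grad += _unbroadcast(bwd_y(g, xt.data, yt.data), yt.data.shape)

    return Tensor(out_data, parents=(xt, yt), backward=backward)


def _unary(x, fwd, bwd):
    if not is_tensor(x):
        return fwd(np.asarray(x, dtype=np.float64))
    out_data = fwd(x.data)

    def backward(g):
        if x.requires_grad:
            x.grad += bwd(g, x.data, out_data)

    return Tensor(out_data, parents=(x,), backward=backward)


def add(x, y):
    return _binary(x, y, lambda a, b: a + b, lambda g, a, b: g, lambda g, a, b: g)


def sub(x, y):
    return _binary(x, y, lambda a, b: a - b, lambda g, a, b: g, lambda g, a, b: -g)


def mul(x, y):
    return _binary(x, y, lambda a, b: a * b, lambda g, a, b: g * b, lambda g, a, b: g * a)


def div(x, y):
    return _binary(x, y, lambda a, b: a / b,
                   lambda g, a, b: g / b,
                   lambda g, a, b: -g * a / (b * b))


def power(x, p: float):
    return _unary(x, lambda a: a ** p, lambda g, a, o: g * p * a ** (p - 1))


def matmul(x, y):
    def bwd_x(g, a, b):
        return g @ np.swapaxes(b, -1, -2)

    def bwd_y(g, a, b):
        return np.swapaxes(a, -1, -2) @ g

    return _binary(x, y, lambda a, b: a @ b, bwd_x, bwd_y)


def sum_(x, axis=None, keepdims=False):
    if not is_tensor(x):
        return np.sum(x, axis=axis, keepdims=keepdims)
    out = np.sum(x.data, axis=axis, keepdims=keepdims)

    def backward(g):
        if not x.requires_grad:
            return
        if axis is None:
            x.grad += np.broadcast_to(g, x.data.shape)
            return
        gg = g
        if not keepdims:
            gg = np.expand_dims(g, axis)
        x.grad += np.broadcast_to(gg, x.data.shape)

    return Tensor(out, parents=(x,), backward=backward)


def mean_(x, axis=None, keepdims=False):
    data = as_array(x)
    if axis is None:
        n = data.size
    else:
        axes = (axis,) if isinstance(axis, int) else axis
        n = int(np.prod([data.shape[a] for a in axes]))
    return div(sum_(x, axis=axis, keepdims=keepdims), float(n))


def exp(x):
    return _unary(x, np.exp, lambda g, a, o: g * o)


def log(x):
    return _unary(x, np.log, lambda g, a, o: g / a)


def sin(x):
    return _unary(x, np.sin, lambda g, a, o: g * np.cos(a))


def cos(x):
    return _unary(x, np.cos, lambda g, a, o: -g * np.sin(a))


def tanh(x):
    return _unary(x, np.tanh, lambda g, a, o: g * (1.0 - o * o))


def sqrt(x):
    return _unary(x, np.sqrt, lambda g, a, o: g * 0.5 / o)


def relu(x):
    return _unary(x, lambda a: np.maximum(a, 0.0), lambda g, a, o: g * (a > 0))


def softplus(x):
    return _unary(x, lambda a: np.logaddexp(0.0, a),
                  lambda g, a, o: g / (1.0 + np.exp(-a)))


def where(cond, x, y):
    """Select by a boolean ndarray condition (the condition itself is constant)."""
    cond = np.asarray(cond)
    return add(mul(x, cond.astype(np.float64)), mul(y, (~cond).astype(np.float64)))


def reshape(x, shape):
    if not is_tensor(x):
        return np.reshape(x, shape)
    out = np.reshape(x.data, shape)

    def backward(g):
        if x.requires_grad:
            x.grad += g.reshape(x.data.shape)

    return Tensor(out, parents=(x,), backward=backward)


def transpose(x, axes):
    if not is_tensor(x):
        return np.transpose(x, axes)
    out = np.transpose(x.data, axes)
    inv = np.argsort(axes)

    def backward(g):
        if x.requires_grad:
            x.grad += np.transpose(g, inv)

    return Tensor(out, parents=(x,), backward=backward)


def broadcast_to(x, shape):
    if not is_tensor(x):
        return np.broadcast_to(x, shape)
    out = np.broadcast_to(x.data, shape)

    def backward(g):
        if x.requires_grad:
            x.grad += _unbroadcast(g, x.data.shape)

    return Tensor(np.ascontiguousarray(out), parents=(x,), backward=backward)


def take(x, idx):
    """Indexing/gather; backward scatter-adds into the source."""
    if not is_tensor(x):
        return np.asarray(x)[idx]
    out = x.data[idx]

    def backward(g):
        if x.requires_grad:
            np.add.at(x.grad, idx, g)

    return Tensor(out, parents=(x,), backward=backward)


def concatenate(parts, axis=0):
    if not any(is_tensor(p) for p in parts):
        return np.concatenate(parts, axis=axis)
    tparts = [p if is_tensor(p) else Tensor(p) for p in parts]
    out = np.concatenate([p.data for p in tparts], axis=axis)
    sizes = [p.data.shape[axis] for p in tparts]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for p, lo, hi in zip(tparts, offsets[:-1], offsets[1:]):
            if p.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                p.grad += g[tuple(sl)]

    return Tensor(out, parents=tuple(tparts), backward=backward)


def stack(parts, axis=0):
    if not any(is_tensor(p) for p in parts):
        return np.stack(parts, axis=axis)
    tparts = [p if is_tensor(p) else Tensor(p) for p in parts]
    out = np.stack([p.data for p in tparts], axis=axis)

    def backward(g):
        for i, p in enumerate(tparts):
            if p.requires_grad:
                p.grad += np.take(g, i, axis=axis)

    return Tensor(out, parents=tuple(tparts), backward=backward)


def softmax(x, axis=-1):
    shift = np.max(as_array(x), axis=axis, keepdims=True)
    e = exp(sub(x, shift))
    return div(e, sum_(e, axis=axis, keepdims=True))


def log_softmax(x, axis=-1):
    shift = np.max(as_array(x), axis=axis, keepdims=True)
    z = sub(x, shift)
    return sub(z, log(sum_(exp(z), axis=axis, keepdims=True)))


def cross(a, b):
    """Cross product over the last axis (length 3)."""
    ax, ay, az = take(a, (..., 0)), take(a, (..., 1)), take(a, (..., 2))
    bx, by, bz = take(b, (..., 0)), take(b, (..., 1)), take(b, (..., 2))
    return stack([
        sub(mul(ay, bz), mul(az, by)),
        sub(mul(az, bx), mul(ax, bz)),
        sub(mul(ax, by), mul(ay, bx)),
    ], axis=-1)


def norm(x, axis=-1, keepdims=False, eps=0.0):
    return sqrt(add(sum_(mul(x, x), axis=axis, keepdims=keepdims), eps))
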