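"""Compact reverse-mode automatic differentiation over dense numpy arrays.

The graph-structure-learning model is transductive and desk-scale (a few
thousand cells), so every intermediate — including the learned N x N
adjacency — fits comfortably in a dense array.  This module provides the
small set of differentiable primitives the model needs (broadcasted
arithmetic, matmul, relu, exp/log, reductions, row gather, a gradient-safe
sqrt), plus the two trainable layers (linear, 1-d batch normalization) and
an Adam optimizer.

All computation is float64 and single-threaded-deterministic: a fixed seed
yields bitwise-identical results on CPU.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "relu",
    "Linear",
    "BatchNorm1d",
    "Adam",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 _parents: tuple = (), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = _parents
        self._backward = _backward

    # -- basic introspection ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- graph construction helpers -----------------------------------------
    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _make(self, data, parents, backward) -> "Tensor":
        req = any(p.requires_grad for p in parents)
        if not req:
            return Tensor(data)
        return Tensor(data, requires_grad=True, _parents=parents, _backward=backward)

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)
        out_data = self.data + other.data

        def backward(g):
            return (_unbroadcast(g, self.data.shape),
                    _unbroadcast(g, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return self._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out_data = self.data * other.data
        a, b = self.data, other.data

        def backward(g):
            return (_unbroadcast(g * b, a.shape), _unbroadcast(g * a, b.shape))

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return self._lift(other) * self ** -1.0

    def __pow__(self, exponent: float):
        e = float(exponent)
        out_data = self.data ** e
        x = self.data

        def backward(g):
            return (g * e * x ** (e - 1.0),)

        return self._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = self._lift(other)
        out_data = self.data @ other.data
        a, b = self.data, other.data

        def backward(g):
            return (g @ b.T, a.T @ g)

        return self._make(out_data, (self, other), backward)

    # -- elementwise nonlinearities ------------------------------------------
    def relu(self):
        mask = self.data > 0

        def backward(g):
            return (g * mask,)

        return self._make(self.data * mask, (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            return (g * out_data,)

        return self._make(out_data, (self,), backward)

    def log(self):
        x = self.data

        def backward(g):
            return (g / x,)

        return self._make(np.log(x), (self,), backward)

    def sqrt_safe(self, floor: float = 1e-12):
        """Exact sqrt value with the gradient clamped near zero.

        d/dx sqrt(x) = 1/(2 sqrt(x)) diverges at 0; the clamp keeps the
        subgradient finite so hinge terms sitting exactly at zero distance
        do not poison the backward pass, while the forward value stays
        exact (sqrt(0) = 0).
        """
        out_data = np.sqrt(self.data)
        denom = 2.0 * np.maximum(out_data, floor)

        def backward(g):
            return (g / denom,)

        return self._make(out_data, (self,), backward)

    # -- reductions and shaping ------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        shape = self.data.shape

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, shape).copy(),)

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        old = self.data.shape

        def backward(g):
            return (g.reshape(old),)

        return self._make(self.data.reshape(*shape), (self,), backward)

    @property
    def T(self):
        def backward(g):
            return (g.T,)

        return self._make(self.data.T, (self,), backward)

    def take_rows(self, index: np.ndarray):
        """Gather rows (differentiable scatter-add on the way back)."""
        index = np.asarray(index)
        shape = self.data.shape

        def backward(g):
            out = np.zeros(shape)
            np.add.at(out, index, g)
            return (out,)

        return self._make(self.data[index], (self,), backward)

    # -- autodiff driver ------------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep
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

        for node in topo:
            node.grad = np.zeros_like(node.data)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is None:
                continue
            grads = node._backward(node.grad)
            for parent, g in zip(node._parents, grads):
                if parent.requires_grad:
                    parent.grad = parent.grad + g if parent.grad is not None else g

    def item(self) -> float:
        return float(self.data)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def relu(x: Tensor) -> Tensor:
    return as_tensor(x).relu()


# ---------------------------------------------------------------------------
# trainable layers
# ---------------------------------------------------------------------------

def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class Linear:
    """Dense affine map x @ W (+ b)."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 bias: bool = True):
        self.W = Tensor(_glorot(rng, in_dim, out_dim), requires_grad=True)
        self.b = Tensor(np.zeros(out_dim), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = as_tensor(x) @ self.W
        if self.b is not None:
            out = out + self.b
        return out

    def parameters(self):
        return [self.W] if self.b is None else [self.W, self.b]


class BatchNorm1d:
    """1-d batch normalization over the leading (cell) axis.

    Training mode normalizes with batch statistics (gradients flow through
    them); evaluation mode uses the exponential running averages
    (momentum 0.1, epsilon 1e-5).
    """

    def __init__(self, dim: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)
        self.momentum = momentum
        self.eps = eps
        self.training = True

    def __call__(self, x: Tensor) -> Tensor:
        x = as_tensor(x)
        if self.training:
            mu = x.mean(axis=0, keepdims=True)
            centered = x - mu
            var = (centered * centered).mean(axis=0, keepdims=True)
            m, v = mu.data.ravel(), var.data.ravel()
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * m
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * v
            xhat = centered * (var + self.eps) ** -0.5
        else:
            xhat = (x - self.running_mean) * (self.running_var + self.eps) ** -0.5
        return xhat * self.gamma + self.beta

    def parameters(self):
        return [self.gamma, self.beta]


class Adam:
    """Adam with classic additive L2 weight decay on the gradient."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
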