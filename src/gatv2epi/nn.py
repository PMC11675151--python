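"""A minimal reverse-mode automatic differentiation engine on numpy arrays.

Just enough machinery for the CNN + graph-attention edge classifier in this
package: broadcasting arithmetic, matmul, slicing/gather, concatenation,
reductions, the activations used by the model, and a segment sum for
per-neighborhood softmax.  Gradients are checked against central finite
differences in the test suite.

The engine is deliberately small: float64 everywhere, no in-place ops, no
graph retention tricks.  ``Tensor.backward()`` runs a topological sweep and
accumulates ``grad`` on every tensor created with ``requires_grad=True``.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce a broadcasted gradient back to ``shape``."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_prev", "_backward")

    def __init__(self, data, requires_grad: bool = False, _prev=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad
        self.grad = None
        self._prev = _prev
        self._backward = _backward

    # -- infrastructure -------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = None
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def _accum(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad = self.grad + g

    # -- arithmetic ------------------------------------------------------

    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def bw(g):
            self._accum(_unbroadcast(g, self.data.shape))
            other._accum(_unbroadcast(g, other.data.shape))
        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _prev=(self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def bw(g):
            self._accum(_unbroadcast(g * other.data, self.data.shape))
            other._accum(_unbroadcast(g * self.data, other.data.shape))
        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data / other.data, _prev=(self, other))

        def bw(g):
            self._accum(_unbroadcast(g / other.data, self.data.shape))
            other._accum(_unbroadcast(-g * self.data / other.data ** 2,
                                      other.data.shape))
        out._backward = bw
        return out

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data @ other.data, _prev=(self, other))

        def bw(g):
            a, b = self.data, other.data
            if a.ndim == 1 and b.ndim == 1:
                self._accum(g * b)
                other._accum(g * a)
            elif a.ndim == 1:
                self._accum(g @ b.T)
                other._accum(np.outer(a, g))
            elif b.ndim == 1:
                self._accum(np.outer(g, b))
                other._accum(a.T @ g)
            else:
                self._accum(g @ np.swapaxes(b, -1, -2))
                other._accum(np.swapaxes(a, -1, -2) @ g)
        out._backward = bw
        return out

    # -- shape ops -------------------------------------------------------

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), _prev=(self,))
        out._backward = lambda g: self._accum(g.reshape(self.data.shape))
        return out

    def __getitem__(self, key):
        out = Tensor(self.data[key], _prev=(self,))

        def bw(g):
            gx = np.zeros_like(self.data)
            np.add.at(gx, key, g)
            self._accum(gx)
        out._backward = bw
        return out

    # -- reductions ------------------------------------------------------

    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))

        def bw(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.data.shape).copy())
        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max_last(self):
        """Max over the trailing axis (used for pooling); ties break to the
        first maximum, matching standard max-pool gradient routing."""
        idx = np.argmax(self.data, axis=-1)
        out = Tensor(np.take_along_axis(self.data, idx[..., None], -1)[..., 0],
                     _prev=(self,))

        def bw(g):
            gx = np.zeros_like(self.data)
            np.put_along_axis(gx, idx[..., None], g[..., None], -1)
            self._accum(gx)
        out._backward = bw
        return out

    # -- activations -----------------------------------------------------

    def leaky_relu(self, slope: float = 0.2):
        out = Tensor(np.where(self.data > 0, self.data, slope * self.data),
                     _prev=(self,))
        out._backward = lambda g: self._accum(
            g * np.where(self.data > 0, 1.0, slope))
        return out

    def relu(self):
        return self.leaky_relu(0.0)

    def elu(self, alpha: float = 1.0):
        neg = alpha * (np.exp(np.minimum(self.data, 0.0)) - 1.0)
        out = Tensor(np.where(self.data > 0, self.data, neg), _prev=(self,))
        out._backward = lambda g: self._accum(
            g * np.where(self.data > 0, 1.0, neg + alpha))
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, _prev=(self,))
        out._backward = lambda g: self._accum(g * s * (1.0 - s))
        return out

    def exp(self):
        e = np.exp(self.data)
        out = Tensor(e, _prev=(self,))
        out._backward = lambda g: self._accum(g * e)
        return out

    def log(self):
        out = Tensor(np.log(self.data), _prev=(self,))
        out._backward = lambda g: self._accum(g / self.data)
        return out

    def softplus(self):
        """log(1 + exp(x)), numerically stable; d/dx = sigmoid(x)."""
        out = Tensor(np.logaddexp(0.0, self.data), _prev=(self,))
        out._backward = lambda g: self._accum(
            g / (1.0 + np.exp(-self.data)))
        return out


def concat(tensors: list, axis: int = 0) -> Tensor:
    tensors = [t if isinstance(t, Tensor) else Tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 _prev=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accum(piece)
    out._backward = bw
    return out


def segment_sum(x: Tensor, segments: np.ndarray, n: int) -> Tensor:
    """Sum rows of ``x`` into ``n`` buckets given per-row segment ids."""
    segments = np.asarray(segments, dtype=int)
    data = np.zeros((n,) + x.data.shape[1:])
    np.add.at(data, segments, x.data)
    out = Tensor(data, _prev=(x,))
    out._backward = lambda g: x._accum(g[segments])
    return out


def segment_softmax(scores: Tensor, segments: np.ndarray, n: int) -> Tensor:
    """Softmax of ``scores`` within each segment (per-query normalization).

    The per-segment max shift is treated as a constant, which leaves the
    gradient exact (softmax is shift-invariant).
    """
    segments = np.asarray(segments, dtype=int)
    mx = np.full(n, -np.inf)
    np.maximum.at(mx, segments, scores.data)
    shifted = scores - Tensor(mx[segments])
    e = shifted.exp()
    denom = segment_sum(e, segments, n)
    return e / denom[segments]


def parameter(data) -> Tensor:
    return Tensor(np.asarray(data, dtype=np.float64), requires_grad=True)


def glorot(rng: np.random.Generator, shape: tuple) -> np.ndarray:
    fan_in = shape[-1] if len(shape) > 1 else shape[0]
    fan_out = shape[0]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Adam:
    """Adam optimizer over a list of parameter tensors."""

    def __init__(self, params: list, lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
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
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
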