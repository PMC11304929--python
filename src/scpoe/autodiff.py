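"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the product-of-experts VAE needs: broadcasted
arithmetic, matrix products, elementwise transcendentals (including ``lgamma``,
whose derivative is the digamma function), axis reductions, concatenation and a
gradient-reversal node for adversarial training.  Gradients of broadcasted
operands are reduced back to the operand's shape, so parameters may be row
vectors (biases) or scalars (dispersions) without special-casing.
"""

from __future__ import annotations

import numpy as np
from scipy.special import digamma, expit, gammaln

__all__ = ["Tensor", "concat", "grad_reverse", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` over axes that were broadcast so it matches `shape`."""
    if grad.shape == shape:
        return grad
    # leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # axes of size 1 that were stretched
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the computation graph wrapping an ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")
    __array_priority__ = 100  # numpy defers binary ops to us

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = parents
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    # -- arithmetic -----------------------------------------------------------

    def __add__(self, other):
        other = self._lift(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.data.shape))

        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = self._lift(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.data.shape))

        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self):
        def backward(g, a=self):
            a._accum(_unbroadcast(-g, a.data.shape))

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __truediv__(self, other):
        other = self._lift(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g / b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(-g * a.data / b.data**2, b.data.shape))

        return self._make(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, exponent: float):
        def backward(g, a=self, n=exponent):
            a._accum(_unbroadcast(g * n * a.data ** (n - 1), a.data.shape))

        return self._make(self.data**exponent, (self,), backward)

    def __matmul__(self, other):
        other = self._lift(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(g @ b.data.T)
            if b.requires_grad:
                b._accum(a.data.T @ g)

        return self._make(self.data @ other.data, (self, other), backward)

    # -- elementwise ----------------------------------------------------------

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g, a=self, d=out_data):
            a._accum(_unbroadcast(g * d, a.data.shape))

        return self._make(out_data, (self,), backward)

    def log(self):
        def backward(g, a=self):
            a._accum(_unbroadcast(g / a.data, a.data.shape))

        return self._make(np.log(self.data), (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g, a=self, m=mask):
            a._accum(_unbroadcast(g * m, a.data.shape))

        return self._make(self.data * mask, (self,), backward)

    def sigmoid(self):
        s = expit(self.data)

        def backward(g, a=self, s=s):
            a._accum(_unbroadcast(g * s * (1 - s), a.data.shape))

        return self._make(s, (self,), backward)

    def softplus(self):
        # numerically stable log(1 + e^x)
        out_data = np.logaddexp(0.0, self.data)
        s = expit(self.data)

        def backward(g, a=self, s=s):
            a._accum(_unbroadcast(g * s, a.data.shape))

        return self._make(out_data, (self,), backward)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(g, a=self, d=out_data):
            a._accum(_unbroadcast(g * 0.5 / d, a.data.shape))

        return self._make(out_data, (self,), backward)

    def lgamma(self):
        def backward(g, a=self):
            a._accum(_unbroadcast(g * digamma(a.data), a.data.shape))

        return self._make(gammaln(self.data), (self,), backward)

    def clip_min(self, low: float):
        """max(x, low); gradient passes only where x > low."""
        mask = self.data > low

        def backward(g, a=self, m=mask):
            a._accum(_unbroadcast(g * m, a.data.shape))

        return self._make(np.maximum(self.data, low), (self,), backward)

    # -- reductions & shape ---------------------------------------------------

    def sum(self, axis=None, keepdims=False):
        def backward(g, a=self, axis=axis, keepdims=keepdims):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            a._accum(np.broadcast_to(g, a.data.shape).copy())

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        def backward(g, a=self):
            a._accum(g.reshape(a.data.shape))

        return self._make(self.data.reshape(*shape), (self,), backward)

    def clip_max(self, high: float):
        """min(x, high); gradient passes only where x < high."""
        mask = self.data < high

        def backward(g, a=self, m=mask):
            a._accum(_unbroadcast(g * m, a.data.shape))

        return self._make(np.minimum(self.data, high), (self,), backward)

    def slice_cols(self, lo: int, hi: int):
        def backward(g, a=self, lo=lo, hi=hi):
            full = np.zeros_like(a.data)
            full[:, lo:hi] = g
            a._accum(full)

        return self._make(self.data[:, lo:hi], (self,), backward)

    def log_softmax(self, axis=-1):
        m = self.data.max(axis=axis, keepdims=True)
        shifted = self.data - m
        lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
        out_data = shifted - lse
        softmax = np.exp(out_data)

        def backward(g, a=self, s=softmax, axis=axis):
            a._accum(g - s * g.sum(axis=axis, keepdims=True))

        return self._make(out_data, (self,), backward)

    # -- autograd driver ------------------------------------------------------

    def _accum(self, g: np.ndarray):
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64)
        else:
            self.grad = self.grad + g

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def zero_grad(self):
        self.grad = None


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    """Differentiable concatenation along `axis`."""
    tensors = [Tensor._lift(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    out = Tensor(data)
    out.requires_grad = any(t.requires_grad for t in tensors)
    if out.requires_grad:
        sizes = [t.data.shape[axis] for t in tensors]
        offsets = np.cumsum([0] + sizes)

        def backward(g):
            for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    idx = [slice(None)] * g.ndim
                    idx[axis] = slice(lo, hi)
                    t._accum(g[tuple(idx)])

        out._parents = tuple(tensors)
        out._backward = backward
    return out


def grad_reverse(x: Tensor, scale: float = 1.0) -> Tensor:
    """Identity in the forward pass; multiplies gradients by -scale backward.

    This is the gradient-reversal layer of Ganin & Lempitsky: placing it
    between the embedding and an adversary lets a single optimisation step
    train the adversary to predict a batch factor while pushing the embedding
    to be uninformative about it.
    """

    def backward(g, a=x, s=scale):
        a._accum(-s * g)

    return x._make(x.data.copy(), (x,), backward)


class Adam:
    """Adam optimiser over a list of parameter Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

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
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
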