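"""A compact reverse-mode automatic-differentiation engine over NumPy arrays.

This is the numerical substrate for the regressive vision transformer: a
tape of :class:`Tensor` nodes, each remembering how to push its output
gradient back to its parents.  The op set is exactly what the encoder,
fusion module, heads and losses need — broadcasted arithmetic, batched
matmul, reshapes, gather/slice, softmax, layer norm, GELU, sigmoid and an
im2col ``unfold`` for convolutions — plus an Adam optimizer.

Arrays keep the dtype they were created with; the model trains in float32
while gradient-check tests run the same graph in float64.
"""

from __future__ import annotations

import contextlib
import math
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy import special as _sp

__all__ = [
    "Tensor", "Parameter", "no_grad", "concat", "matmul", "where",
    "softmax", "log_softmax", "layer_norm", "gelu", "sigmoid", "unfold",
    "Adam",
]

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction inside the block (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A node in the autodiff tape wrapping an ``ndarray``."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "_grad_borrowed")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward: Callable[[np.ndarray], None] | None = None
        self._grad_borrowed = False

    # -- graph plumbing ---------------------------------------------------
    @staticmethod
    def _make(data: np.ndarray, parents: Sequence["Tensor"],
              backward: Callable[[np.ndarray], None]) -> "Tensor":
        track = _GRAD_ENABLED and any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=track)
        if track:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accumulate(self, grad: np.ndarray) -> None:
        # First contribution is stored by reference ("borrowed": it may be
        # shared with another node, e.g. both residual branches); a second
        # contribution forces a fresh buffer before in-place accumulation.
        if self.grad is None:
            if grad.dtype != self.data.dtype:
                grad = grad.astype(self.data.dtype)
            self.grad = grad
            self._grad_borrowed = True
        elif self._grad_borrowed:
            self.grad = self.grad + grad
            self._grad_borrowed = False
        else:
            self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this node (default seed: ones)."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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
                if id(p) not in seen:
                    stack.append((p, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- basic properties -------------------------------------------------
    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic -------------------------------------------------------
    @staticmethod
    def _coerce(x, like: "Tensor") -> "Tensor":
        if isinstance(x, Tensor):
            return x
        return Tensor(np.asarray(x, dtype=like.data.dtype))

    def __add__(self, other):
        other = self._coerce(other, self)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g, b.data.shape))
        return Tensor._make(a.data + b.data, (a, b), backward)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def backward(g):
            if a.requires_grad:
                a._accumulate(-g)
        return Tensor._make(-a.data, (a,), backward)

    def __sub__(self, other):
        return self + (-self._coerce(other, self))

    def __rsub__(self, other):
        return self._coerce(other, self) + (-self)

    def __mul__(self, other):
        other = self._coerce(other, self)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g * a.data, b.data.shape))
        return Tensor._make(a.data * b.data, (a, b), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other, self)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g / b.data, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(-g * a.data / (b.data * b.data), b.data.shape))
        return Tensor._make(a.data / b.data, (a, b), backward)

    def __rtruediv__(self, other):
        return self._coerce(other, self) / self

    def __pow__(self, p: float):
        a = self

        def backward(g):
            if a.requires_grad:
                a._accumulate(g * p * a.data ** (p - 1))
        return Tensor._make(a.data ** p, (a,), backward)

    def __matmul__(self, other):
        return matmul(self, self._coerce(other, self))

    # -- shape ops --------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        old = a.data.shape

        def backward(g):
            if a.requires_grad:
                a._accumulate(g.reshape(old))
        return Tensor._make(a.data.reshape(shape), (a,), backward)

    def transpose(self, axes: Sequence[int]):
        a = self
        axes = tuple(axes)
        inv = tuple(np.argsort(axes))

        def backward(g):
            if a.requires_grad:
                a._accumulate(g.transpose(inv))
        return Tensor._make(a.data.transpose(axes), (a,), backward)

    def swapaxes(self, i: int, j: int):
        order = list(range(self.data.ndim))
        order[i], order[j] = order[j], order[i]
        return self.transpose(order)

    def __getitem__(self, idx):
        a = self

        def backward(g):
            if a.requires_grad:
                ga = np.zeros_like(a.data)
                np.add.at(ga, idx, g)
                a._accumulate(ga)
        return Tensor._make(a.data[idx], (a,), backward)

    # -- reductions -------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self

        def backward(g):
            if not a.requires_grad:
                return
            if axis is None:
                a._accumulate(np.broadcast_to(g, a.data.shape))
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            a._accumulate(np.broadcast_to(gg, a.data.shape))
        return Tensor._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[ax] for ax in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- elementwise nonlinearities ---------------------------------------
    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def backward(g):
            if a.requires_grad:
                a._accumulate(g * out_data)
        return Tensor._make(out_data, (a,), backward)

    def log(self):
        a = self

        def backward(g):
            if a.requires_grad:
                a._accumulate(g / a.data)
        return Tensor._make(np.log(a.data), (a,), backward)

    def sqrt(self):
        a = self
        out_data = np.sqrt(a.data)

        def backward(g):
            if a.requires_grad:
                a._accumulate(g * (0.5 / out_data))
        return Tensor._make(out_data, (a,), backward)

    def tanh(self):
        a = self
        out_data = np.tanh(a.data)

        def backward(g):
            if a.requires_grad:
                a._accumulate(g * (1.0 - out_data * out_data))
        return Tensor._make(out_data, (a,), backward)


class Parameter(Tensor):
    """A trainable tensor."""

    __slots__ = ()

    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


# -- free-function ops ----------------------------------------------------

def matmul(a: Tensor, b: Tensor) -> Tensor:
    """Batched matrix product with NumPy broadcasting on leading axes."""

    def backward(g):
        if a.requires_grad:
            ga = g @ b.data.swapaxes(-1, -2)
            a._accumulate(_unbroadcast(ga, a.data.shape))
        if b.requires_grad:
            gb = a.data.swapaxes(-1, -2) @ g
            b._accumulate(_unbroadcast(gb, b.data.shape))
    return Tensor._make(a.data @ b.data, (a, b), backward)


def concat(tensors: Iterable[Tensor], axis: int = -1) -> Tensor:
    ts = list(tensors)
    sizes = [t.data.shape[axis] for t in ts]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        pieces = np.split(g, splits, axis=axis)
        for t, piece in zip(ts, pieces):
            if t.requires_grad:
                t._accumulate(piece)
    return Tensor._make(np.concatenate([t.data for t in ts], axis=axis), ts, backward)


def where(cond: np.ndarray, a: Tensor, b: Tensor) -> Tensor:
    """Elementwise select; ``cond`` is a constant boolean mask."""
    cond = np.asarray(cond, dtype=bool)

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(np.where(cond, g, 0.0), a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(np.where(cond, 0.0, g), b.data.shape))
    return Tensor._make(np.where(cond, a.data, b.data), (a, b), backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        if x.requires_grad:
            gx = y * (g - (g * y).sum(axis=axis, keepdims=True))
            x._accumulate(gx)
    return Tensor._make(y, (x,), backward)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
    out = z - lse
    sm = np.exp(out)

    def backward(g):
        if x.requires_grad:
            x._accumulate(g - sm * g.sum(axis=axis, keepdims=True))
    return Tensor._make(out, (x,), backward)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Layer normalization over the last axis with affine parameters."""
    mu = x.data.mean(axis=-1, keepdims=True)
    xc = x.data - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out = xhat * gamma.data + beta.data

    def backward(g):
        if gamma.requires_grad:
            gamma._accumulate(_unbroadcast(g * xhat, gamma.data.shape))
        if beta.requires_grad:
            beta._accumulate(_unbroadcast(g, beta.data.shape))
        if x.requires_grad:
            gh = g * gamma.data
            gx = inv * (gh - gh.mean(axis=-1, keepdims=True)
                        - xhat * (gh * xhat).mean(axis=-1, keepdims=True))
            x._accumulate(gx)
    return Tensor._make(out, (x, gamma, beta), backward)


_INV_SQRT2 = 1.0 / math.sqrt(2.0)
_INV_SQRT2PI = 1.0 / math.sqrt(2.0 * math.pi)


def gelu(x: Tensor) -> Tensor:
    """Exact Gaussian-error linear unit ``x * Phi(x)``."""
    phi_cdf = 0.5 * (1.0 + _sp.erf(x.data * _INV_SQRT2))
    out = x.data * phi_cdf

    def backward(g):
        if x.requires_grad:
            pdf = np.exp(-0.5 * x.data * x.data) * _INV_SQRT2PI
            x._accumulate(g * (phi_cdf + x.data * pdf))
    return Tensor._make(out, (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    y = _sp.expit(x.data)

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * y * (1.0 - y))
    return Tensor._make(y, (x,), backward)


def unfold(x: Tensor, kernel: int, stride: int, pad: int) -> Tensor:
    """im2col: ``(B,H,W,C) -> (B,Ho,Wo,kernel*kernel*C)`` patches.

    Zero padding of ``pad`` pixels on each spatial border; ``Ho = (H + 2*pad
    - kernel)//stride + 1`` and likewise ``Wo``.
    """
    B, H, W, C = x.data.shape
    xp = np.pad(x.data, ((0, 0), (pad, pad), (pad, pad), (0, 0))) if pad else x.data
    Hp, Wp = H + 2 * pad, W + 2 * pad
    Ho = (Hp - kernel) // stride + 1
    Wo = (Wp - kernel) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (kernel, kernel), axis=(1, 2))
    win = win[:, ::stride, ::stride]                  # (B,Ho,Wo,C,k,k)
    out = np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3)).reshape(B, Ho, Wo, kernel * kernel * C)

    def backward(g):
        if not x.requires_grad:
            return
        gg = g.reshape(B, Ho, Wo, kernel, kernel, C)
        gx = np.zeros((B, Hp, Wp, C), dtype=x.data.dtype)
        for i in range(kernel):
            for j in range(kernel):
                gx[:, i:i + Ho * stride:stride, j:j + Wo * stride:stride] += gg[:, :, :, i, j]
        if pad:
            gx = gx[:, pad:-pad, pad:-pad]
        x._accumulate(gx)
    return Tensor._make(out, (x,), backward)


# -- optimizer ------------------------------------------------------------

class Adam:
    """Adam with bias correction (Kingma & Ba) over a list of Parameters."""

    def __init__(self, params: Iterable[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * (g * g)
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
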