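"""Minimal reverse-mode automatic differentiation over NumPy arrays.

This is the tensor core the network and its training loops run on. It is a
deliberately small, dependency-free tape machine: each op records its parents
and a closure that accumulates gradients into them. Only the operations the
spectrogram transformer needs are implemented (broadcast arithmetic, batched
matmul, 2-D convolution and frequency max-pooling, GELU, softmax, layer norm,
embedding gather, masked reductions, cross-entropy). Computation uses
float32 by default (set ``DEFAULT_DTYPE`` to float64 for gradient checks);
single-threaded NumPy keeps results bit-reproducible for fixed seeds.
"""

from __future__ import annotations

import math
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.special import erf

try:                                    # pin BLAS to one thread: keeps
    import threadpoolctl                # float32 reductions bit-identical
    threadpoolctl.threadpool_limits(limits=1)   # across machines
except Exception:                       # pragma: no cover
    pass

DEFAULT_DTYPE = np.float32

__all__ = [
    "DEFAULT_DTYPE",
    "Tensor",
    "Parameter",
    "Adam",
    "gelu",
    "softmax",
    "layer_norm",
    "conv2d",
    "maxpool_freq2",
    "embedding",
    "cross_entropy",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndim_extra = grad.ndim - len(shape)
    if ndim_extra > 0:
        grad = grad.sum(axis=tuple(range(ndim_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """An array node on the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=DEFAULT_DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data: np.ndarray, parents: Sequence["Tensor"],
              backward: Callable[[np.ndarray], None]) -> "Tensor":
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- arithmetic -----------------------------------------------------------

    def __add__(self, other) -> "Tensor":
        other = self._lift(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def backward(g):
            self._accum(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other) -> "Tensor":
        return self + (-self._lift(other))

    def __rsub__(self, other) -> "Tensor":
        return self._lift(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = self._lift(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        if isinstance(other, Tensor):
            return self * other ** -1.0
        return self * (1.0 / other)

    def __pow__(self, p: float) -> "Tensor":
        def backward(g):
            self._accum(g * p * self.data ** (p - 1))

        return self._make(self.data ** p, (self,), backward)

    def __matmul__(self, other) -> "Tensor":
        other = self._lift(other)

        def backward(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.shape))

        return self._make(self.data @ other.data, (self, other), backward)

    # -- shape ops ------------------------------------------------------------

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape

        def backward(g):
            self._accum(g.reshape(old))

        return self._make(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes) -> "Tensor":
        if not axes:
            axes = tuple(reversed(range(self.ndim)))
        inv = np.argsort(axes)

        def backward(g):
            self._accum(g.transpose(inv))

        return self._make(self.data.transpose(axes), (self,), backward)

    def swapaxes(self, a: int, b: int) -> "Tensor":
        def backward(g):
            self._accum(np.swapaxes(g, a, b))

        return self._make(np.swapaxes(self.data, a, b), (self,), backward)

    # -- reductions -----------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        def backward(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.shape).copy())

        return self._make(self.data.sum(axis=axis, keepdims=keepdims),
                          (self,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- autodiff driver ------------------------------------------------------

    def _accum(self, g: np.ndarray) -> None:
        # gradients are accumulated without in-place mutation, so adopting
        # the incoming array by reference is safe
        if self.grad is None:
            self.grad = np.asarray(g, dtype=self.data.dtype)
        else:
            self.grad = self.grad + g

    def backward(self) -> None:
        """Reverse sweep from this (scalar) tensor."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


# ---------------------------------------------------------------------------
# fused ops


def gelu(x: Tensor) -> Tensor:
    """Exact (erf-based) Gaussian Error Linear Unit."""
    xd = x.data
    cdf = 0.5 * (1.0 + erf(xd / math.sqrt(2.0)))
    out_data = xd * cdf

    def backward(g):
        pdf = np.exp(-0.5 * xd * xd) / math.sqrt(2.0 * math.pi)
        x._accum(g * (cdf + xd * pdf))

    return x._make(out_data, (x,), backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    xd = x.data
    m = xd.max(axis=axis, keepdims=True)
    e = np.exp(xd - m)
    s = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * s).sum(axis=axis, keepdims=True)
        x._accum(s * (g - dot))

    return x._make(s, (x,), backward)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor,
               eps: float = 1e-5) -> Tensor:
    """Normalize over the last axis, then scale and shift."""
    xd = x.data
    mu = xd.mean(axis=-1, keepdims=True)
    var = xd.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (xd - mu) * inv
    out_data = xhat * gamma.data + beta.data
    n = xd.shape[-1]

    def backward(g):
        if gamma.requires_grad:
            gamma._accum(_unbroadcast(g * xhat, gamma.shape))
        if beta.requires_grad:
            beta._accum(_unbroadcast(g, beta.shape))
        if x.requires_grad:
            gx = g * gamma.data
            term = gx - gx.mean(axis=-1, keepdims=True) \
                - xhat * (gx * xhat).mean(axis=-1, keepdims=True)
            x._accum(term * inv)

    return x._make(out_data, (x, gamma, beta), backward)


def conv2d(x: Tensor, weight: Tensor, bias: Tensor, padding: int) -> Tensor:
    """Same-stride 2-D convolution, NCHW layout, square kernel.

    Implemented as a sum over kernel offsets, each a (O,C)x(B,C,H,W)
    contraction; memory-light and exactly differentiable.
    """
    B, C, H, W = x.shape
    O, Ck, KH, KW = weight.shape
    if Ck != C:
        raise ValueError("channel mismatch")
    p = padding
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)))
    Ho, Wo = H + 2 * p - KH + 1, W + 2 * p - KW + 1
    # im2col once, then a single GEMM: (O, C*KH*KW) x (C*KH*KW, B*Ho*Wo)
    view = np.lib.stride_tricks.sliding_window_view(xp, (KH, KW),
                                                    axis=(2, 3))
    cols = np.ascontiguousarray(view.transpose(1, 4, 5, 0, 2, 3)).reshape(
        C * KH * KW, B * Ho * Wo)
    w2 = weight.data.reshape(O, C * KH * KW)
    out_data = (w2 @ cols).reshape(O, B, Ho, Wo).swapaxes(0, 1) \
        + bias.data.reshape(1, O, 1, 1)

    def backward(g):
        if bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2, 3)))
        g2 = np.ascontiguousarray(g.swapaxes(0, 1)).reshape(O, B * Ho * Wo)
        if weight.requires_grad:
            weight._accum((g2 @ cols.T).reshape(weight.shape))
        if x.requires_grad:
            gcols = (w2.T @ g2).reshape(C, KH, KW, B, Ho, Wo)
            gxp = np.zeros_like(xp)
            for dy in range(KH):
                for dx in range(KW):
                    gxp[:, :, dy:dy + Ho, dx:dx + Wo] += \
                        gcols[:, dy, dx].swapaxes(0, 1).reshape(B, C, Ho, Wo)
            x._accum(gxp[:, :, p:p + H, p:p + W])

    return x._make(out_data, (x, weight, bias), backward)


def maxpool_freq2(x: Tensor) -> Tensor:
    """Max-pool of kernel (2,1): halves the frequency axis (floor), keeps time."""
    B, C, H, W = x.shape
    H2 = H // 2
    a = x.data[:, :, 0:2 * H2:2, :]
    b = x.data[:, :, 1:2 * H2:2, :]
    take_a = a >= b                     # ties route the gradient upward
    out_data = np.where(take_a, a, b)

    def backward(g):
        full = np.zeros_like(x.data)
        full[:, :, 0:2 * H2:2, :] = np.where(take_a, g, 0.0)
        full[:, :, 1:2 * H2:2, :] = np.where(take_a, 0.0, g)
        x._accum(full)

    return x._make(out_data, (x,), backward)


def embedding(table: Tensor, idx: np.ndarray) -> Tensor:
    """Gather rows of `table` by an integer index array."""
    idx = np.asarray(idx)
    out_data = table.data[idx]

    def backward(g):
        flat_idx = idx.ravel()
        g2 = g.reshape(-1, table.shape[-1])
        rows, dims = table.shape
        acc = np.empty((rows, dims), dtype=table.data.dtype)
        for d in range(dims):
            acc[:, d] = np.bincount(flat_idx, weights=g2[:, d],
                                    minlength=rows)
        table._accum(acc)

    return table._make(out_data, (table,), backward)


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of (N, K) logits against integer labels."""
    labels = np.asarray(labels)
    ld = logits.data
    m = ld.max(axis=1, keepdims=True)
    e = np.exp(ld - m)
    p = e / e.sum(axis=1, keepdims=True)
    n = ld.shape[0]
    nll = -np.log(np.maximum(p[np.arange(n), labels], 1e-300)).mean()

    def backward(g):
        gp = p.copy()
        gp[np.arange(n), labels] -= 1.0
        logits._accum(g * gp / n)

    return logits._make(np.array(nll), (logits,), backward)


# ---------------------------------------------------------------------------
# optimizer


class Adam:
    """Adam with the standard bias correction (Kingma & Ba)."""

    def __init__(self, params: Iterable[Parameter], lr: float = 3e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * p.grad
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * p.grad ** 2
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
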