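"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The package's neural components (graph encoder, transformer encoder, omics
subnetworks, convolutional head) are small enough to train on a CPU, so the
engine favours clarity over throughput: every operation is a NumPy float64
computation that records a backward closure, and :meth:`Tensor.backward`
replays them in reverse topological order.

Only the operations the encoders actually use are implemented.  Gradient
correctness is verified against central finite differences in the test suite.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "AdamW", "concat", "as_tensor"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum away prepended axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple["Tensor", ...] = (),
                 backward: Callable[[np.ndarray], None] | None = None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # -- bookkeeping ------------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; graphs can exceed the recursion limit
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
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -------------------------------------------------------

    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))
        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))

        def bwd(g):
            self._accum(-g)
        out._backward = bwd
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))
        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data / other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g * self.data / other.data ** 2,
                                          other.data.shape))
        out._backward = bwd
        return out

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, parents=(self,))

        def bwd(g):
            self._accum(g * p * self.data ** (p - 1))
        out._backward = bwd
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.data.shape))
        out._backward = bwd
        return out

    # -- elementwise nonlinearities ---------------------------------------

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), parents=(self,))

        def bwd(g):
            self._accum(g * (self.data > 0))
        out._backward = bwd
        return out

    def tanh(self):
        y = np.tanh(self.data)
        out = Tensor(y, parents=(self,))

        def bwd(g):
            self._accum(g * (1.0 - y ** 2))
        out._backward = bwd
        return out

    def exp(self):
        y = np.exp(self.data)
        out = Tensor(y, parents=(self,))

        def bwd(g):
            self._accum(g * y)
        out._backward = bwd
        return out

    def log(self):
        out = Tensor(np.log(self.data), parents=(self,))

        def bwd(g):
            self._accum(g / self.data)
        out._backward = bwd
        return out

    def sqrt(self):
        return self ** 0.5

    # -- reductions -------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def bwd(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())
        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False):
        y = self.data.max(axis=axis, keepdims=True)
        mask = (self.data == y)
        mask = mask / mask.sum(axis=axis, keepdims=True)  # split ties evenly
        out = Tensor(y if keepdims else np.squeeze(y, axis), parents=(self,))

        def bwd(g):
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(g * mask)
        out._backward = bwd
        return out

    def softmax(self, axis: int = -1):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        y = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(y, parents=(self,))

        def bwd(g):
            dot = (g * y).sum(axis=axis, keepdims=True)
            self._accum(y * (g - dot))
        out._backward = bwd
        return out

    # -- shape manipulation -----------------------------------------------

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), parents=(self,))

        def bwd(g):
            self._accum(g.reshape(self.data.shape))
        out._backward = bwd
        return out

    def transpose(self, *axes):
        axes = axes or tuple(reversed(range(self.ndim)))
        out = Tensor(self.data.transpose(axes), parents=(self,))

        def bwd(g):
            self._accum(g.transpose(np.argsort(axes)))
        out._backward = bwd
        return out

    @property
    def T(self):
        return self.transpose()

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], parents=(self,))

        def bwd(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)
        out._backward = bwd
        return out

    # -- 1D convolution / pooling (batch, channels, length) ---------------

    def conv1d(self, weight: "Tensor", bias: "Tensor"):
        """Valid cross-correlation, stride 1. self: (B,Ci,L); weight: (Co,Ci,K)."""
        x, w = self.data, weight.data
        B, Ci, L = x.shape
        Co, _, K = w.shape
        Lo = L - K + 1
        y = np.zeros((B, Co, Lo))
        for k in range(K):
            y += np.einsum("bcl,oc->bol", x[:, :, k:k + Lo], w[:, :, k])
        y += bias.data[None, :, None]
        out = Tensor(y, parents=(self, weight, bias))

        def bwd(g):
            if self.requires_grad:
                gx = np.zeros_like(x)
                for k in range(K):
                    gx[:, :, k:k + Lo] += np.einsum("bol,oc->bcl", g, w[:, :, k])
                self._accum(gx)
            if weight.requires_grad:
                gw = np.zeros_like(w)
                for k in range(K):
                    gw[:, :, k] = np.einsum("bol,bcl->oc", g, x[:, :, k:k + Lo])
                weight._accum(gw)
            if bias.requires_grad:
                bias._accum(g.sum(axis=(0, 2)))
        out._backward = bwd
        return out

    def maxpool1d(self, size: int = 2):
        """Non-overlapping max pooling over the last axis; remainder dropped."""
        x = self.data
        B, C, L = x.shape
        Lo = L // size
        win = x[:, :, :Lo * size].reshape(B, C, Lo, size)
        idx = win.argmax(axis=-1)
        out = Tensor(win.max(axis=-1), parents=(self,))

        def bwd(g):
            gx = np.zeros_like(x)
            gwin = gx[:, :, :Lo * size].reshape(B, C, Lo, size)
            np.put_along_axis(gwin, idx[..., None], g[..., None], axis=-1)
            gx[:, :, :Lo * size] = gwin.reshape(B, C, Lo * size)
            self._accum(gx)
        out._backward = bwd
        return out

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])
    out._backward = bwd
    return out


class AdamW(object):
    """AdamW with decoupled weight decay (Loshchilov & Hutter)."""

    def __init__(self, params: Iterable[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr, self.betas, self.eps, self.weight_decay = lr, betas, eps, weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad ** 2
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data -= self.lr * (mhat / (np.sqrt(vhat) + self.eps)
                                 + self.weight_decay * p.data)
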