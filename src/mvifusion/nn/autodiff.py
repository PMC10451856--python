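"""Minimal reverse-mode automatic differentiation on NumPy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations that
produced it; calling :meth:`Tensor.backward` on a scalar accumulates
gradients into every upstream tensor with ``requires_grad``.  The op set is
exactly what the attention networks need: broadcast arithmetic, (batched)
matmul, reshape/transpose/concat, reductions, ReLU/exp/log, a numerically
stable softmax and cross-entropy, 3D convolution via im2col, and 2x2x2 max
pooling.  Graphs are built per forward pass and discarded after the backward
sweep.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (the inverse of NumPy broadcasting)."""
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
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[], None] | None = None

    # -- graph plumbing ---------------------------------------------------
    @staticmethod
    def _make(data: np.ndarray, parents: Sequence["Tensor"], backward: Callable[[], None]) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            # copy: upstream may hand us (a view of) its own grad buffer
            self.grad = np.array(grad, dtype=grad.dtype)
        else:
            self.grad += grad

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs can be deep
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
                node._backward()

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def _coerce(self, other) -> "Tensor":
        # Python scalars adopt this tensor's dtype: NumPy 2 would otherwise
        # promote float32 graphs to float64 through 0-d float64 operands.
        if isinstance(other, (int, float)):
            return Tensor(np.asarray(other, dtype=self.data.dtype))
        return as_tensor(other)

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = self._coerce(other)
        out_data = self.data + other.data

        def bw():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad, other.data.shape))

        out = Tensor._make(out_data, (self, other), bw)
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = self._coerce(other)
        out_data = self.data * other.data

        def bw():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad * self.data, other.data.shape))

        out = Tensor._make(out_data, (self, other), bw)
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __truediv__(self, scalar: float):
        return self * (1.0 / float(scalar))

    def __matmul__(self, other):
        other = as_tensor(other)
        out_data = np.matmul(self.data, other.data)

        def bw():
            g = out.grad
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accum(_unbroadcast(gb, other.data.shape))

        out = Tensor._make(out_data, (self, other), bw)
        return out

    # -- shape ops --------------------------------------------------------
    def reshape(self, *shape):
        shape = shape[0] if len(shape) == 1 and isinstance(shape[0], tuple) else shape
        out_data = self.data.reshape(shape)

        def bw():
            if self.requires_grad:
                self._accum(out.grad.reshape(self.data.shape))

        out = Tensor._make(out_data, (self,), bw)
        return out

    def transpose(self, *axes):
        out_data = np.transpose(self.data, axes)
        inv = np.argsort(axes)

        def bw():
            if self.requires_grad:
                self._accum(np.transpose(out.grad, inv))

        out = Tensor._make(out_data, (self,), bw)
        return out

    # -- reductions -------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bw():
            if self.requires_grad:
                g = out.grad
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.data.shape).copy())

        out = Tensor._make(out_data, (self,), bw)
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod([self.data.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- nonlinearities ---------------------------------------------------
    def relu(self):
        mask = self.data > 0
        out_data = self.data * mask

        def bw():
            if self.requires_grad:
                self._accum(out.grad * mask)

        out = Tensor._make(out_data, (self,), bw)
        return out

    def exp(self):
        out_data = np.exp(self.data)

        def bw():
            if self.requires_grad:
                self._accum(out.grad * out_data)

        out = Tensor._make(out_data, (self,), bw)
        return out

    def log(self):
        out_data = np.log(self.data)

        def bw():
            if self.requires_grad:
                self._accum(out.grad / self.data)

        out = Tensor._make(out_data, (self,), bw)
        return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw():
        parts = np.split(out.grad, splits, axis=axis)
        for t, g in zip(tensors, parts):
            if t.requires_grad:
                t._accum(g)

    out = Tensor._make(out_data, tuple(tensors), bw)
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)

    def bw():
        if x.requires_grad:
            g = out.grad
            dot = (g * s).sum(axis=axis, keepdims=True)
            x._accum(s * (g - dot))

    out = Tensor._make(s, (x,), bw)
    return out


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of integer ``labels`` under row-softmax of ``logits``."""
    labels = np.asarray(labels, dtype=int)
    z = logits.data - logits.data.max(axis=-1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=-1, keepdims=True)
    n = labels.shape[0]
    nll = -np.log(np.clip(p[np.arange(n), labels], 1e-300, None)).mean()

    def bw():
        if logits.requires_grad:
            g = p.copy()
            g[np.arange(n), labels] -= 1.0
            logits._accum(out.grad * g / n)

    out = Tensor._make(np.asarray(nll), (logits,), bw)
    return out


def conv3d(x: Tensor, weight: Tensor, bias: Tensor, kernel: int = 3, pad: int = 1) -> Tensor:
    """3D convolution, stride 1.

    ``x``: (B, C_in, D, H, W); ``weight``: (C_out, C_in * kernel^3);
    ``bias``: (C_out,).  Output: (B, C_out, D, H, W) for pad = (kernel-1)/2.
    """
    B, C, D, H, W = x.data.shape
    k = kernel
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad), (pad, pad)))
    Do, Ho, Wo = D + 2 * pad - k + 1, H + 2 * pad - k + 1, W + 2 * pad - k + 1
    N = Do * Ho * Wo
    # im2col in one strided copy; cols rows are (offset, C_in) flattened,
    # matching the weight layout
    sw = np.lib.stride_tricks.sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))
    cols = sw.transpose(0, 5, 6, 7, 1, 2, 3, 4).reshape(B, k * k * k * C, N)
    out_data = np.matmul(weight.data, cols) + bias.data[:, None]
    out_data = out_data.reshape(B, weight.data.shape[0], Do, Ho, Wo)

    def bw():
        g = out.grad.reshape(B, weight.data.shape[0], N)
        if bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2)))
        if weight.requires_grad:
            gw = np.matmul(g, cols.swapaxes(1, 2)).sum(axis=0)  # (C_out, C*k^3)
            weight._accum(gw.astype(weight.data.dtype))
        if x.requires_grad:
            dcols = np.matmul(weight.data.T, g)  # (B, C*k^3, N)
            dxp = np.zeros_like(xp)
            i = 0
            for di in range(k):
                for hj in range(k):
                    for wk in range(k):
                        dxp[:, :, di : di + Do, hj : hj + Ho, wk : wk + Wo] += dcols[
                            :, i * C : (i + 1) * C, :
                        ].reshape(B, C, Do, Ho, Wo)
                        i += 1
            x._accum(dxp[:, :, pad : pad + D, pad : pad + H, pad : pad + W])

    out = Tensor._make(out_data, (x, weight, bias), bw)
    return out


def maxpool3d(x: Tensor, k: int = 2) -> Tensor:
    """Non-overlapping k^3 max pooling; dims must be divisible by ``k``."""
    B, C, D, H, W = x.data.shape
    if D % k or H % k or W % k:
        raise ValueError(f"spatial dims {(D, H, W)} not divisible by pool size {k}")
    d, h, w = D // k, H // k, W // k
    win = x.data.reshape(B, C, d, k, h, k, w, k).transpose(0, 1, 2, 4, 6, 3, 5, 7).reshape(B, C, d, h, w, k**3)
    arg = win.argmax(axis=-1)
    out_data = np.take_along_axis(win, arg[..., None], axis=-1)[..., 0]

    def bw():
        if x.requires_grad:
            gwin = np.zeros_like(win)
            np.put_along_axis(gwin, arg[..., None], out.grad[..., None], axis=-1)
            gx = (
                gwin.reshape(B, C, d, h, w, k, k, k)
                .transpose(0, 1, 2, 5, 3, 6, 4, 7)
                .reshape(B, C, D, H, W)
            )
            x._accum(gx)

    out = Tensor._make(out_data, (x,), bw)
    return out
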