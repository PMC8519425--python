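"""Reverse-mode automatic differentiation on NumPy arrays.

A deliberately small tape-based engine: a :class:`Tensor` wraps an
``ndarray``, records the operations applied to it, and :meth:`Tensor.backward`
propagates gradients through the recorded graph in reverse topological order.
Only the operations needed by the dense U-Net generators, the patch
discriminator and the training losses are provided, but each is implemented
with an exact analytic backward pass (verified against finite differences in
the test suite).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor", "as_tensor"]


def _sum_to_shape(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce a broadcast gradient back to ``shape``."""
    if grad.shape == shape:
        return grad
    # sum leading broadcast axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An ndarray with an optional gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = _parents
        self._backward = _backward

    # ------------------------------------------------------------------ basic
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    @property
    def dtype(self):
        return self.data.dtype

    def item(self) -> float:
        return float(self.data)

    def __float__(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # ------------------------------------------------------------- graph glue
    @staticmethod
    def _make(data, parents, backward):
        req = any(p.requires_grad for p in parents)
        if not req:
            return Tensor(data)
        return Tensor(data, requires_grad=True, _parents=parents, _backward=backward)

    def _accumulate(self, grad: np.ndarray):
        if self.grad is None:
            self.grad = grad.copy() if isinstance(grad, np.ndarray) else np.asarray(grad)
        else:
            self.grad = self.grad + grad

    def backward(self, grad=None):
        """Backpropagate from this tensor (a scalar unless ``grad`` is given)."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
        # iterative topological sort
        topo, visited, stack = [], set(), [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited or not node.requires_grad:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)
            # free the closure so intermediate buffers can be collected
            node._backward = None
            node._parents = ()

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = as_tensor(other)

        def backward(g):
            if self.requires_grad:
                self._accumulate(_sum_to_shape(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_sum_to_shape(g, other.data.shape))

        return Tensor._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accumulate(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)

        def backward(g):
            if self.requires_grad:
                self._accumulate(_sum_to_shape(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_sum_to_shape(g * self.data, other.data.shape))

        return Tensor._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, (int, float)):
            return self * (1.0 / other)
        raise TypeError("Tensor division only supports scalars")

    def __pow__(self, exponent: float):
        def backward(g):
            self._accumulate(g * exponent * self.data ** (exponent - 1))

        return Tensor._make(self.data**exponent, (self,), backward)

    def abs(self):
        def backward(g):
            self._accumulate(g * np.sign(self.data))

        return Tensor._make(np.abs(self.data), (self,), backward)

    def sum(self):
        def backward(g):
            self._accumulate(np.broadcast_to(g, self.data.shape).astype(self.data.dtype))

        return Tensor._make(self.data.sum(), (self,), backward)

    def mean(self):
        n = self.data.size

        def backward(g):
            self._accumulate(np.broadcast_to(g / n, self.data.shape).astype(self.data.dtype))

        return Tensor._make(self.data.mean(), (self,), backward)

    def __getitem__(self, idx):
        def backward(g):
            dz = np.zeros_like(self.data)
            dz[idx] += g
            self._accumulate(dz)

        return Tensor._make(self.data[idx], (self,), backward)

    def reshape(self, *shape):
        orig = self.data.shape

        def backward(g):
            self._accumulate(g.reshape(orig))

        return Tensor._make(self.data.reshape(*shape), (self,), backward)

    # ---------------------------------------------------------- nonlinearities
    def relu(self):
        mask = self.data > 0

        def backward(g):
            self._accumulate(g * mask)

        return Tensor._make(self.data * mask, (self,), backward)

    def leaky_relu(self, slope: float = 0.2):
        mask = self.data > 0

        def backward(g):
            self._accumulate(g * np.where(mask, 1.0, slope))

        return Tensor._make(np.where(mask, self.data, slope * self.data), (self,), backward)

    def sigmoid(self):
        out = _sigmoid(self.data)

        def backward(g):
            self._accumulate(g * out * (1.0 - out))

        return Tensor._make(out, (self,), backward)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=x.dtype if x.dtype.kind == "f" else np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def as_tensor(x) -> Tensor:
    if isinstance(x, Tensor):
        return x
    return Tensor(np.asarray(x))


# ======================================================================= ops
def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), backward)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1, padding: int = 0) -> Tensor:
    """2-D cross-correlation over NCHW input with OIHW weights."""
    x, w = as_tensor(x), as_tensor(w)
    n, c = x.data.shape[0], x.data.shape[1]
    o, kh, kw = w.data.shape[0], w.data.shape[2], w.data.shape[3]
    s = stride
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding))) if padding else x.data
    windows = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::s, ::s]
    ho, wo = windows.shape[2], windows.shape[3]
    # im2col + GEMM: one big copy, one big matmul
    col = np.ascontiguousarray(windows.transpose(0, 2, 3, 1, 4, 5)).reshape(
        n * ho * wo, c * kh * kw)
    wmat = w.data.reshape(o, c * kh * kw)
    out = (col @ wmat.T).reshape(n, ho, wo, o).transpose(0, 3, 1, 2)
    out = np.ascontiguousarray(out)
    if b is not None:
        out += b.data[None, :, None, None]

    def backward(g):
        gmat = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(n * ho * wo, o)
        if w.requires_grad:
            dw = (gmat.T @ col).reshape(o, c, kh, kw)
            w._accumulate(dw.astype(w.data.dtype, copy=False))
        if b is not None and b.requires_grad:
            b._accumulate(gmat.sum(axis=0).astype(b.data.dtype, copy=False))
        if x.requires_grad:
            if s == 1:
                # dx = full correlation of g with the flipped kernel (GEMM path)
                gp = np.pad(g, ((0, 0), (0, 0), (kh - 1, kh - 1), (kw - 1, kw - 1)))
                gwin = sliding_window_view(gp, (kh, kw), axis=(2, 3))
                gcol = np.ascontiguousarray(gwin.transpose(0, 2, 3, 1, 4, 5)).reshape(
                    n * (ho + kh - 1) * (wo + kw - 1), o * kh * kw)
                wflip = w.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3).reshape(c, o * kh * kw)
                dxp = (gcol @ wflip.T).reshape(n, ho + kh - 1, wo + kw - 1, c).transpose(0, 3, 1, 2)
            else:
                dcol = (gmat @ wmat).reshape(n, ho, wo, c, kh, kw)
                dxp = np.zeros_like(xp)
                for u in range(kh):
                    for v in range(kw):
                        dxp[:, :, u : u + s * ho : s, v : v + s * wo : s] += \
                            dcol[:, :, :, :, u, v].transpose(0, 3, 1, 2)
            if padding:
                dxp = dxp[:, :, padding:-padding, padding:-padding]
            x._accumulate(np.ascontiguousarray(dxp))

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._make(out, parents, backward)


def batch_norm2d(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    x = as_tensor(x)
    if training:
        mu = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mu, var = running_mean, running_var
    std = np.sqrt(var + eps)
    xhat = (x.data - mu[None, :, None, None]) / std[None, :, None, None]
    out = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]
    m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]

    def backward(g):
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)).astype(gamma.data.dtype, copy=False))
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=(0, 2, 3)).astype(beta.data.dtype, copy=False))
        if x.requires_grad:
            dxhat = g * gamma.data[None, :, None, None]
            if training:
                # standard batch-norm backward through batch statistics
                t1 = dxhat.sum(axis=(0, 2, 3), keepdims=True)
                t2 = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
                mu_ax = mu[None, :, None, None]
                dx = (dxhat - t1 / m - xhat * t2 / m) / std[None, :, None, None]
                del mu_ax
            else:
                dx = dxhat / std[None, :, None, None]
            x._accumulate(dx)

    return Tensor._make(out, (x, gamma, beta), backward)


def max_pool2d(x: Tensor, k: int = 2) -> Tensor:
    x = as_tensor(x)
    n, c, h, w = x.data.shape
    if h % k or w % k:
        raise ValueError(f"max_pool2d requires H,W divisible by {k}, got {h}x{w}")
    xv = x.data.reshape(n, c, h // k, k, w // k, k)
    out = xv.max(axis=(3, 5))

    def backward(g):
        mask = xv == out[:, :, :, None, :, None]
        counts = mask.sum(axis=(3, 5), keepdims=True)
        dx = mask * (g[:, :, :, None, :, None] / counts)
        x._accumulate(dx.reshape(n, c, h, w))

    return Tensor._make(out, (x,), backward)


def pixel_shuffle(x: Tensor, r: int = 2) -> Tensor:
    x = as_tensor(x)
    n, c, h, w = x.data.shape
    if c % (r * r):
        raise ValueError("channel count not divisible by r^2")
    co = c // (r * r)
    out = (
        x.data.reshape(n, co, r, r, h, w)
        .transpose(0, 1, 4, 2, 5, 3)
        .reshape(n, co, h * r, w * r)
    )

    def backward(g):
        dx = (
            g.reshape(n, co, h, r, w, r)
            .transpose(0, 1, 3, 5, 2, 4)
            .reshape(n, c, h, w)
        )
        x._accumulate(dx)

    return Tensor._make(np.ascontiguousarray(out), (x,), backward)


def dropout(x: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    if not training or p <= 0.0:
        return x
    x = as_tensor(x)
    keep = rng.random(x.data.shape) >= p
    scale = 1.0 / (1.0 - p)
    mask = keep * scale

    def backward(g):
        x._accumulate(g * mask)

    return Tensor._make(x.data * mask, (x,), backward)


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy computed stably from logits."""
    logits = as_tensor(logits)
    t = np.asarray(targets, dtype=float)
    z = logits.data
    loss = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))
    n = z.size

    def backward(g):
        logits._accumulate(g * (_sigmoid(z) - t) / n)

    return Tensor._make(loss.mean(), (logits,), backward)
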