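"""Reverse-mode automatic differentiation on NumPy arrays.

A deliberately small define-by-run tape: each :class:`Tensor` wraps an
``ndarray`` and remembers how to push gradients to its parents.  The op set is
exactly what the segmentation network needs — elementwise arithmetic, matmul,
reductions, 3x3/1x1 convolution via im2col, 2x pooling/upsampling, softmax,
bilinear (deformable) sampling and a straight-through clamp.  Everything runs
in float32 by default; float64 inputs are preserved so finite-difference
gradient checks can run at full precision.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor", "as_tensor", "concat", "softmax", "conv2d", "avg_pool2",
    "upsample2", "deform_sample", "no_grad", "is_grad_enabled",
]

_GRAD_ENABLED = [True]


class no_grad:
    """Context manager disabling tape construction (inference mode)."""

    def __enter__(self):
        _GRAD_ENABLED.append(False)
        return self

    def __exit__(self, *exc):
        _GRAD_ENABLED.pop()
        return False


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED[-1]


def _coerce(data) -> np.ndarray:
    arr = np.asarray(data)
    if arr.dtype not in (np.float32, np.float64):
        arr = arr.astype(np.float32)
    return arr


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, (g, s) in enumerate(zip(grad.shape, shape)) if s == 1 and g != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _coerce(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = ()

    # -- graph bookkeeping -------------------------------------------------
    @classmethod
    def _make(cls, data, parents, backward):
        out = cls(data)
        if is_grad_enabled() and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, g):
        g = _unbroadcast(np.asarray(g, dtype=self.data.dtype), self.data.shape)
        if self.grad is None:
            self.grad = g
        else:
            self.grad = self.grad + g

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self._accum(grad)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # -- conveniences ------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        o = as_tensor(other)
        out = Tensor._make(self.data + o.data, (self, o), None)

        def bw(g):
            if self.requires_grad:
                self._accum(g)
            if o.requires_grad:
                o._accum(g)
        out._backward = bw if out.requires_grad else None
        return out

    __radd__ = __add__

    def __mul__(self, other):
        o = as_tensor(other)
        out = Tensor._make(self.data * o.data, (self, o), None)

        def bw(g):
            if self.requires_grad:
                self._accum(g * o.data)
            if o.requires_grad:
                o._accum(g * self.data)
        out._backward = bw if out.requires_grad else None
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __truediv__(self, other):
        o = as_tensor(other)
        out = Tensor._make(self.data / o.data, (self, o), None)

        def bw(g):
            if self.requires_grad:
                self._accum(g / o.data)
            if o.requires_grad:
                o._accum(-g * self.data / (o.data * o.data))
        out._backward = bw if out.requires_grad else None
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        out = Tensor._make(self.data ** exponent, (self,), None)

        def bw(g):
            self._accum(g * exponent * self.data ** (exponent - 1))
        out._backward = bw if out.requires_grad else None
        return out

    def __matmul__(self, other):
        o = as_tensor(other)
        out = Tensor._make(self.data @ o.data, (self, o), None)

        def bw(g):
            if self.requires_grad:
                self._accum(g @ np.swapaxes(o.data, -1, -2))
            if o.requires_grad:
                o._accum(np.swapaxes(self.data, -1, -2) @ g)
        out._backward = bw if out.requires_grad else None
        return out

    def __getitem__(self, idx):
        out = Tensor._make(self.data[idx], (self,), None)

        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)
        out._backward = bw if out.requires_grad else None
        return out

    # -- elementwise nonlinearities ---------------------------------------
    def exp(self):
        y = np.exp(self.data)
        out = Tensor._make(y, (self,), None)
        out._backward = (lambda g: self._accum(g * y)) if out.requires_grad else None
        return out

    def log(self):
        out = Tensor._make(np.log(self.data), (self,), None)
        out._backward = (lambda g: self._accum(g / self.data)) if out.requires_grad else None
        return out

    def sqrt(self):
        y = np.sqrt(self.data)
        out = Tensor._make(y, (self,), None)
        out._backward = (lambda g: self._accum(g * 0.5 / y)) if out.requires_grad else None
        return out

    def sigmoid(self):
        x = self.data
        y = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))),
                     np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))))
        out = Tensor._make(y, (self,), None)
        out._backward = (lambda g: self._accum(g * y * (1.0 - y))) if out.requires_grad else None
        return out

    def softplus(self):
        y = np.logaddexp(np.zeros((), dtype=self.data.dtype), self.data)
        out = Tensor._make(y, (self,), None)
        if out.requires_grad:
            x = self.data
            sig = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))),
                           np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))))
            out._backward = lambda g: self._accum(g * sig)
        return out

    def tanh(self):
        y = np.tanh(self.data)
        out = Tensor._make(y, (self,), None)
        out._backward = (lambda g: self._accum(g * (1.0 - y * y))) if out.requires_grad else None
        return out

    def abs(self):
        s = np.sign(self.data)
        out = Tensor._make(np.abs(self.data), (self,), None)
        out._backward = (lambda g: self._accum(g * s)) if out.requires_grad else None
        return out

    def relu(self):
        mask = self.data > 0
        out = Tensor._make(self.data * mask, (self,), None)
        out._backward = (lambda g: self._accum(g * mask)) if out.requires_grad else None
        return out

    def clip(self, lo: float, hi: float):
        """Clamp with zero gradient outside [lo, hi]."""
        inside = (self.data >= lo) & (self.data <= hi)
        out = Tensor._make(np.clip(self.data, lo, hi), (self,), None)
        out._backward = (lambda g: self._accum(g * inside)) if out.requires_grad else None
        return out

    def clip_st(self, lo: float, hi: float):
        """Clamp with a straight-through gradient: forward saturates, the
        gradient passes unchanged so saturated regions can still recover."""
        out = Tensor._make(np.clip(self.data, lo, hi), (self,), None)
        out._backward = (lambda g: self._accum(g)) if out.requires_grad else None
        return out

    # -- reductions & shape ops -------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), None)

        def bw(g):
            if axis is not None and not keepdims:
                ax = axis if isinstance(axis, tuple) else (axis,)
                g = np.expand_dims(g, ax)
            self._accum(np.broadcast_to(g, self.data.shape))
        out._backward = bw if out.requires_grad else None
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis, keepdims=False):
        y = self.data.max(axis=axis, keepdims=True)
        out_data = y if keepdims else np.squeeze(y, axis=axis)
        out = Tensor._make(out_data, (self,), None)

        def bw(g):
            if not keepdims:
                g = np.expand_dims(g, axis)
            mask = (self.data == y)
            counts = mask.sum(axis=axis, keepdims=True)
            self._accum(g * mask / counts)
        out._backward = bw if out.requires_grad else None
        return out

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor._make(self.data.reshape(shape), (self,), None)
        out._backward = (lambda g: self._accum(g.reshape(self.data.shape))) if out.requires_grad else None
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = Tensor._make(self.data.transpose(axes), (self,), None)
        out._backward = (lambda g: self._accum(g.transpose(inv))) if out.requires_grad else None
        return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor._make(np.concatenate([t.data for t in tensors], axis=axis), tensors, None)
    if out.requires_grad:
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]

        def bw(g):
            for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
                if t.requires_grad:
                    t._accum(piece)
        out._backward = bw
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)
    out = Tensor._make(y, (x,), None)

    def bw(g):
        x._accum(y * (g - (g * y).sum(axis=axis, keepdims=True)))
    out._backward = bw if out.requires_grad else None
    return out


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, padding: int = 0) -> Tensor:
    """2-D convolution (cross-correlation), stride 1, zero padding."""
    B, C, H, W = x.data.shape
    Co, Ci, k, k2 = w.data.shape
    assert Ci == C and k == k2, "kernel/channel mismatch"
    p = padding
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
    win = sliding_window_view(xp, (k, k), axis=(2, 3))  # B,C,Ho,Wo,k,k
    Ho, Wo = win.shape[2], win.shape[3]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(B * Ho * Wo, C * k * k)
    wf = w.data.reshape(Co, -1)
    out_data = cols @ wf.T
    if b is not None:
        out_data = out_data + b.data
    out_data = out_data.reshape(B, Ho, Wo, Co).transpose(0, 3, 1, 2)
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor._make(out_data, parents, None)

    def bw(g):
        gf = g.transpose(0, 2, 3, 1).reshape(B * Ho * Wo, Co)
        if w.requires_grad:
            w._accum((gf.T @ cols).reshape(w.data.shape))
        if b is not None and b.requires_grad:
            b._accum(gf.sum(axis=0))
        if x.requires_grad:
            # (B,Ho,Wo,C,k,k) -> (B,C,k,k,Ho,Wo) in one copy, then shifted adds
            dcols = (gf @ wf).reshape(B, Ho, Wo, C, k, k).transpose(0, 3, 4, 5, 1, 2).copy()
            gxp = np.zeros_like(xp)
            for i in range(k):
                for j in range(k):
                    gxp[:, :, i:i + Ho, j:j + Wo] += dcols[:, :, i, j]
            x._accum(gxp[:, :, p:p + H, p:p + W] if p else gxp)
    out._backward = bw if out.requires_grad else None
    return out


def avg_pool2(x: Tensor) -> Tensor:
    B, C, H, W = x.data.shape
    y = x.data.reshape(B, C, H // 2, 2, W // 2, 2).mean(axis=(3, 5))
    out = Tensor._make(y, (x,), None)

    def bw(g):
        gx = np.repeat(np.repeat(g, 2, axis=2), 2, axis=3) * 0.25
        x._accum(gx)
    out._backward = bw if out.requires_grad else None
    return out


def upsample2(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x upsampling."""
    B, C, H, W = x.data.shape
    y = np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3)
    out = Tensor._make(y, (x,), None)

    def bw(g):
        x._accum(g.reshape(B, C, H, 2, W, 2).sum(axis=(3, 5)))
    out._backward = bw if out.requires_grad else None
    return out


def deform_sample(x: Tensor, offsets: Tensor, kernel: int = 3) -> Tensor:
    """Bilinear sampling at offset kernel taps (the core of deformable conv).

    For every output location and each of the k*k kernel taps, samples the
    input at ``base + tap + offset`` with bilinear interpolation and zero
    out-of-bounds values.  ``offsets`` has 2*k*k channels ordered
    (dy_0, dx_0, dy_1, dx_1, ...).  Returns a (B, C*k*k, H, W) map; a 1x1
    convolution on top completes the deformable convolution.
    """
    B, C, H, W = x.data.shape
    k = kernel
    assert offsets.data.shape == (B, 2 * k * k, H, W)
    taps = [(i - k // 2, j - k // 2) for i in range(k) for j in range(k)]
    gy, gx = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
    out_data = np.empty((B, C * k * k, H, W), dtype=x.data.dtype)
    cache = []
    for t, (dy, dx) in enumerate(taps):
        py = gy + dy + offsets.data[:, 2 * t]       # (B,H,W)
        px = gx + dx + offsets.data[:, 2 * t + 1]
        y0 = np.floor(py).astype(np.int64)
        x0 = np.floor(px).astype(np.int64)
        wy = (py - y0).astype(x.data.dtype)
        wx = (px - x0).astype(x.data.dtype)
        corners = []
        for cy, cx, cw in (
            (y0, x0, (1 - wy) * (1 - wx)),
            (y0, x0 + 1, (1 - wy) * wx),
            (y0 + 1, x0, wy * (1 - wx)),
            (y0 + 1, x0 + 1, wy * wx),
        ):
            valid = (cy >= 0) & (cy < H) & (cx >= 0) & (cx < W)
            cyc = np.clip(cy, 0, H - 1)
            cxc = np.clip(cx, 0, W - 1)
            corners.append((cyc, cxc, cw * valid, valid))
        bidx = np.arange(B)[:, None, None]
        acc = np.zeros((B, C, H, W), dtype=x.data.dtype)
        vals = []
        for cyc, cxc, cw, valid in corners:
            v = x.data[bidx, :, cyc, cxc].transpose(0, 3, 1, 2)  # B,C,H,W
            v = v * valid[:, None]
            vals.append(v)
            acc += v * cw[:, None]
        out_data[:, t * C:(t + 1) * C] = acc
        cache.append((y0, x0, wy, wx, corners, vals))
    out = Tensor._make(out_data, (x, offsets), None)

    def bw(g):
        gx_full = np.zeros_like(x.data) if x.requires_grad else None
        goff = np.zeros_like(offsets.data) if offsets.requires_grad else None
        bidx = np.arange(B)[:, None, None]
        for t in range(len(taps)):
            gt = g[:, t * C:(t + 1) * C]  # B,C,H,W
            y0, x0, wy, wx, corners, vals = cache[t]
            if gx_full is not None:
                for cyc, cxc, cw, valid in corners:
                    contrib = (gt * cw[:, None]).transpose(0, 2, 3, 1)  # B,H,W,C
                    np.add.at(gx_full, (bidx, slice(None), cyc, cxc), contrib)
            if goff is not None:
                v00, v01, v10, v11 = vals
                d_wy = ((v10 - v00) * (1 - wx)[:, None] + (v11 - v01) * wx[:, None])
                d_wx = ((v01 - v00) * (1 - wy)[:, None] + (v11 - v10) * wy[:, None])
                goff[:, 2 * t] = (gt * d_wy).sum(axis=1)
                goff[:, 2 * t + 1] = (gt * d_wx).sum(axis=1)
        if gx_full is not None:
            x._accum(gx_full)
        if goff is not None:
            offsets._accum(goff)
    out._backward = bw if out.requires_grad else None
    return out
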