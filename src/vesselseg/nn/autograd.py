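"""Minimal reverse-mode automatic differentiation over numpy arrays.

The engine is deliberately small: a :class:`Tensor` wraps an ``ndarray``,
records its parents and a backward closure, and :meth:`Tensor.backward`
replays the tape in reverse topological order.  Only the operations needed
by the segmentation networks are provided, each with a fused, vectorised
backward pass (no per-element graph nodes).

All floating point work is done in float32; gradients accumulate in the
same dtype.  Randomness never touches a global generator — callers pass
``numpy.random.Generator`` instances explicitly.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.special import expit

DTYPE = np.float32

_grad_enabled = True


@contextlib.contextmanager
def no_grad():
    """Context manager disabling tape construction (inference mode)."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


def grad_enabled() -> bool:
    return _grad_enabled


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], None] | None = None

    # -- graph bookkeeping -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(DTYPE, copy=True)
        else:
            self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self) -> None:
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
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operator sugar ----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    def __mul__(self, other):
        return mul(self, other)

    def __matmul__(self, other):
        return matmul(self, other)

    def reshape(self, *shape):
        return reshape(self, shape)

    def transpose(self, *axes):
        return transpose(self, axes)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data: np.ndarray, parents: Sequence[Tensor],
          backward: Callable[[np.ndarray], None]) -> Tensor:
    out = Tensor(data)
    if _grad_enabled and any(p.requires_grad or p._parents for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce a broadcast gradient back to ``shape``."""
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# elementwise / shape ops
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data + b.data

    def backward(g):
        a._accumulate(_unbroadcast(g, a.shape))
        b._accumulate(_unbroadcast(g, b.shape))

    return _make(data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data * b.data

    def backward(g):
        a._accumulate(_unbroadcast(g * b.data, a.shape))
        b._accumulate(_unbroadcast(g * a.data, b.shape))

    return _make(data, (a, b), backward)


def scale(a, s: float) -> Tensor:
    a = _as_tensor(a)
    data = a.data * DTYPE(s)

    def backward(g):
        a._accumulate(g * DTYPE(s))

    return _make(data, (a,), backward)


def matmul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data @ b.data

    def backward(g):
        ga = g @ np.swapaxes(b.data, -1, -2)
        gb = np.swapaxes(a.data, -1, -2) @ g
        a._accumulate(_unbroadcast(ga, a.shape))
        b._accumulate(_unbroadcast(gb, b.shape))

    return _make(data, (a, b), backward)


def relu(a) -> Tensor:
    a = _as_tensor(a)
    mask = a.data > 0
    data = np.where(mask, a.data, 0)

    def backward(g):
        a._accumulate(g * mask)

    return _make(data, (a,), backward)


def sigmoid(a) -> Tensor:
    a = _as_tensor(a)
    s = expit(a.data)

    def backward(g):
        a._accumulate(g * s * (1.0 - s))

    return _make(s, (a,), backward)


def reshape(a, shape) -> Tensor:
    a = _as_tensor(a)
    old = a.shape
    data = a.data.reshape(shape)

    def backward(g):
        a._accumulate(g.reshape(old))

    return _make(data, (a,), backward)


def transpose(a, axes) -> Tensor:
    a = _as_tensor(a)
    axes = tuple(axes)
    inv = tuple(np.argsort(axes))
    data = a.data.transpose(axes)

    def backward(g):
        a._accumulate(g.transpose(inv))

    return _make(data, (a,), backward)


def concat(tensors: Iterable[Tensor], axis: int) -> Tensor:
    ts = [_as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in ts]
    data = np.concatenate([t.data for t in ts], axis=axis)
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            t._accumulate(g[tuple(idx)])

    return _make(data, tuple(ts), backward)


def mean(a) -> Tensor:
    a = _as_tensor(a)
    n = a.data.size
    data = np.asarray(a.data.mean())

    def backward(g):
        a._accumulate(np.full(a.shape, g / n, dtype=DTYPE))

    return _make(data, (a,), backward)


def softmax(a, axis: int = -1) -> Tensor:
    a = _as_tensor(a)
    z = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * s).sum(axis=axis, keepdims=True)
        a._accumulate(s * (g - dot))

    return _make(s, (a,), backward)


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy from pre-sigmoid scores (numerically stable)."""
    z = logits.data
    y = np.asarray(targets, dtype=DTYPE)
    loss = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
    data = np.asarray(loss.mean())
    n = z.size

    def backward(g):
        p = expit(z)
        logits._accumulate(((g / n) * (p - y)).astype(DTYPE))

    return _make(data, (logits,), backward)


# ---------------------------------------------------------------------------
# spatial ops (NCHW layout)
# ---------------------------------------------------------------------------

def _im2col(xp: np.ndarray, kh: int, kw: int, stride: int, dilation: int,
            oh: int, ow: int) -> np.ndarray:
    b, c = xp.shape[:2]
    cols = np.empty((b, c, kh, kw, oh, ow), dtype=xp.dtype)
    for i in range(kh):
        for j in range(kw):
            r0, c0 = i * dilation, j * dilation
            cols[:, :, i, j] = xp[:, :, r0:r0 + stride * oh:stride,
                                  c0:c0 + stride * ow:stride]
    return cols


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None,
           stride: int = 1, padding: int = 0, dilation: int = 1) -> Tensor:
    """2-D convolution; ``x`` is B×C×H×W, ``weight`` is Cout×Cin×kh×kw."""
    b, cin, h, w = x.shape
    cout, cin_w, kh, kw = weight.shape
    if cin != cin_w:
        raise ValueError(f"conv2d channel mismatch: {cin} vs {cin_w}")
    eff_h, eff_w = dilation * (kh - 1) + 1, dilation * (kw - 1) + 1
    oh = (h + 2 * padding - eff_h) // stride + 1
    ow = (w + 2 * padding - eff_w) // stride + 1
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    cols = _im2col(xp, kh, kw, stride, dilation, oh, ow)
    colsr = cols.reshape(b, cin * kh * kw, oh * ow)
    w2 = weight.data.reshape(cout, cin * kh * kw)
    out = (w2 @ colsr).reshape(b, cout, oh, ow)
    if bias is not None:
        out += bias.data.reshape(1, cout, 1, 1)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        gr = g.reshape(b, cout, oh * ow)
        gw = np.einsum("bop,bcp->oc", gr, colsr, optimize=True)
        weight._accumulate(gw.reshape(weight.shape))
        if bias is not None:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        dcols = (w2.T @ gr).reshape(b, cin, kh, kw, oh, ow)
        dxp = np.zeros_like(xp)
        for i in range(kh):
            for j in range(kw):
                r0, c0 = i * dilation, j * dilation
                dxp[:, :, r0:r0 + stride * oh:stride,
                    c0:c0 + stride * ow:stride] += dcols[:, :, i, j]
        if padding:
            dxp = dxp[:, :, padding:padding + h, padding:padding + w]
        x._accumulate(dxp)

    return _make(out, parents, backward)


def conv_transpose2d(x: Tensor, weight: Tensor, bias: Tensor | None,
                     stride: int = 1) -> Tensor:
    """Transposed convolution; ``weight`` is Cin×Cout×kh×kw (no padding)."""
    b, cin, h, w = x.shape
    cin_w, cout, kh, kw = weight.shape
    if cin != cin_w:
        raise ValueError(f"conv_transpose2d channel mismatch: {cin} vs {cin_w}")
    oh, ow = (h - 1) * stride + kh, (w - 1) * stride + kw
    t = np.einsum("bchw,cokl->boklhw", x.data, weight.data, optimize=True)
    out = np.zeros((b, cout, oh, ow), dtype=DTYPE)
    for i in range(kh):
        for j in range(kw):
            out[:, :, i:i + stride * h:stride, j:j + stride * w:stride] += t[:, :, i, j]
    if bias is not None:
        out += bias.data.reshape(1, cout, 1, 1)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        dt = np.empty((b, cout, kh, kw, h, w), dtype=DTYPE)
        for i in range(kh):
            for j in range(kw):
                dt[:, :, i, j] = g[:, :, i:i + stride * h:stride,
                                   j:j + stride * w:stride]
        x._accumulate(np.einsum("boklhw,cokl->bchw", dt, weight.data,
                                optimize=True))
        weight._accumulate(np.einsum("bchw,boklhw->cokl", x.data, dt,
                                     optimize=True))
        if bias is not None:
            bias._accumulate(g.sum(axis=(0, 2, 3)))

    return _make(out, parents, backward)


def max_pool2d(x: Tensor, k: int = 2) -> Tensor:
    """Non-overlapping max pooling (kernel == stride == k)."""
    b, c, h, w = x.shape
    if h % k or w % k:
        raise ValueError(f"max_pool2d: spatial size {(h, w)} not divisible by {k}")
    oh, ow = h // k, w // k
    xr = x.data.reshape(b, c, oh, k, ow, k).transpose(0, 1, 2, 4, 3, 5)
    xr = xr.reshape(b, c, oh, ow, k * k)
    idx = xr.argmax(axis=-1)
    out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        dxr = np.zeros((b, c, oh, ow, k * k), dtype=DTYPE)
        np.put_along_axis(dxr, idx[..., None], g[..., None], axis=-1)
        dx = dxr.reshape(b, c, oh, ow, k, k).transpose(0, 1, 2, 4, 3, 5)
        x._accumulate(dx.reshape(b, c, h, w))

    return _make(out, (x,), backward)


def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor,
               running_mean: np.ndarray, running_var: np.ndarray,
               training: bool, momentum: float = 0.1,
               eps: float = 1e-5) -> Tensor:
    """Batch normalisation over (B, H, W) per channel; mutates running stats
    in place when training."""
    c = x.shape[1]
    axes = (0, 2, 3)
    if training:
        mu = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        running_mean *= 1 - momentum
        running_mean += momentum * mu
        running_var *= 1 - momentum
        running_var += momentum * var
    else:
        mu, var = running_mean, running_var
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu.reshape(1, c, 1, 1)) * inv.reshape(1, c, 1, 1)
    out = gamma.data.reshape(1, c, 1, 1) * xhat + beta.data.reshape(1, c, 1, 1)

    def backward(g):
        gamma._accumulate((g * xhat).sum(axis=axes))
        beta._accumulate(g.sum(axis=axes))
        gs = g * gamma.data.reshape(1, c, 1, 1)
        if training:
            m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
            mean_gs = gs.mean(axis=axes).reshape(1, c, 1, 1)
            mean_gx = (gs * xhat).mean(axis=axes).reshape(1, c, 1, 1)
            dx = inv.reshape(1, c, 1, 1) * (gs - mean_gs - xhat * mean_gx)
        else:
            dx = gs * inv.reshape(1, c, 1, 1)
        x._accumulate(dx.astype(DTYPE))

    return _make(out.astype(DTYPE), (x, gamma, beta), backward)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor,
               eps: float = 1e-5) -> Tensor:
    """Layer normalisation over the last axis (token embeddings)."""
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out = gamma.data * xhat + beta.data

    def backward(g):
        red = tuple(range(g.ndim - 1))
        gamma._accumulate((g * xhat).sum(axis=red))
        beta._accumulate(g.sum(axis=red))
        gs = g * gamma.data
        mean_gs = gs.mean(axis=-1, keepdims=True)
        mean_gx = (gs * xhat).mean(axis=-1, keepdims=True)
        x._accumulate((inv * (gs - mean_gs - xhat * mean_gx)).astype(DTYPE))

    return _make(out.astype(DTYPE), (x, gamma, beta), backward)
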