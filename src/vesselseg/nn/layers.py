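"""Neural-network layer modules on top of the autograd engine.

Modules follow a torch-like protocol: they own :class:`Parameter` leaves,
expose ``named_parameters`` with dotted paths, and carry a train/eval mode
flag that batch-norm consults.  Every module takes an explicit
``numpy.random.Generator`` for weight initialisation so model construction
is reproducible from a single seed.
"""

from __future__ import annotations

import hashlib
from typing import Iterator

import numpy as np

from . import autograd as ag
from .autograd import DTYPE, Tensor


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    def __init__(self):
        self.training = True

    # -- parameter traversal -------------------------------------------------
    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, value in vars(self).items():
            path = f"{prefix}{name}"
            if isinstance(value, Parameter):
                yield path, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{path}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{path}.{i}.")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def modules(self) -> Iterator["Module"]:
        yield self
        for value in vars(self).values():
            if isinstance(value, Module):
                yield from value.modules()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield from item.modules()

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    # -- state (de)serialisation ----------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, m in self._named_modules():
            if isinstance(m, BatchNorm2d):
                state[f"{name}.running_mean"] = m.running_mean.copy()
                state[f"{name}.running_var"] = m.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, p in self.named_parameters():
            p.data = np.asarray(state[name], dtype=DTYPE).reshape(p.shape)
        for name, m in self._named_modules():
            if isinstance(m, BatchNorm2d):
                m.running_mean[:] = state[f"{name}.running_mean"]
                m.running_var[:] = state[f"{name}.running_var"]

    def _named_modules(self, prefix: str = "") -> Iterator[tuple[str, "Module"]]:
        yield prefix.rstrip("."), self
        for name, value in vars(self).items():
            path = f"{prefix}{name}"
            if isinstance(value, Module):
                yield from value._named_modules(f"{path}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item._named_modules(f"{path}.{i}.")

    def parameter_hash(self) -> str:
        """SHA-256 over all parameter and running-stat bytes, in name order."""
        h = hashlib.sha256()
        for name in sorted(self.state_dict()):
            h.update(name.encode())
            h.update(np.ascontiguousarray(self.state_dict()[name]).tobytes())
        return h.hexdigest()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _kaiming(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(DTYPE)


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator,
                 stride: int = 1, padding: int = 0, dilation: int = 1,
                 bias: bool = True):
        super().__init__()
        self.stride, self.padding, self.dilation = stride, padding, dilation
        self.weight = Parameter(_kaiming(rng, (cout, cin, k, k), cin * k * k))
        self.bias = Parameter(np.zeros(cout, dtype=DTYPE)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return ag.conv2d(x, self.weight, self.bias, self.stride,
                         self.padding, self.dilation)


class ConvTranspose2d(Module):
    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator,
                 stride: int = 1, bias: bool = True):
        super().__init__()
        self.stride = stride
        self.weight = Parameter(_kaiming(rng, (cin, cout, k, k), cin * k * k))
        self.bias = Parameter(np.zeros(cout, dtype=DTYPE)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return ag.conv_transpose2d(x, self.weight, self.bias, self.stride)


class Linear(Module):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        self.weight = Parameter(_kaiming(rng, (cin, cout), cin))
        self.bias = Parameter(np.zeros(cout, dtype=DTYPE)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = ag.matmul(x, self.weight)
        if self.bias is not None:
            out = ag.add(out, self.bias)
        return out


class BatchNorm2d(Module):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(c, dtype=DTYPE))
        self.beta = Parameter(np.zeros(c, dtype=DTYPE))
        self.running_mean = np.zeros(c, dtype=DTYPE)
        self.running_var = np.ones(c, dtype=DTYPE)
        self.momentum, self.eps = momentum, eps

    def forward(self, x: Tensor) -> Tensor:
        return ag.batch_norm(x, self.gamma, self.beta, self.running_mean,
                             self.running_var, self.training,
                             self.momentum, self.eps)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(dim, dtype=DTYPE))
        self.beta = Parameter(np.zeros(dim, dtype=DTYPE))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        return ag.layer_norm(x, self.gamma, self.beta, self.eps)


class MultiHeadSelfAttention(Module):
    """Scaled dot-product self-attention over (B, N, D) token sequences."""

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        if dim % n_heads:
            raise ValueError(f"n_heads={n_heads} must divide dim={dim}")
        self.dim, self.n_heads = dim, n_heads
        self.qkv = Linear(dim, 3 * dim, rng)
        self.proj = Linear(dim, dim, rng)

    def attention_weights(self, x: Tensor) -> np.ndarray:
        """Inference-only attention map (B, heads, N, N) for inspection."""
        with ag.no_grad():
            b, n, d = x.shape
            hd = d // self.n_heads
            qkv = self.qkv(x).data.reshape(b, n, 3, self.n_heads, hd)
            q = qkv[:, :, 0].transpose(0, 2, 1, 3)
            k = qkv[:, :, 1].transpose(0, 2, 1, 3)
            scores = (q @ k.transpose(0, 1, 3, 2)) / np.sqrt(hd)
            scores -= scores.max(axis=-1, keepdims=True)
            e = np.exp(scores)
            return e / e.sum(axis=-1, keepdims=True)

    def forward(self, x: Tensor) -> Tensor:
        b, n, d = x.shape
        h, hd = self.n_heads, d // self.n_heads
        qkv = self.qkv(x)                                      # B,N,3D
        qkv = ag.reshape(qkv, (b, n, 3, h, hd))
        qkv = ag.transpose(qkv, (2, 0, 3, 1, 4))               # 3,B,h,N,hd
        qs = _index0(qkv, 0)
        ks = _index0(qkv, 1)
        vs = _index0(qkv, 2)
        scores = ag.matmul(qs, ag.transpose(ks, (0, 1, 3, 2)))
        scores = ag.scale(scores, 1.0 / np.sqrt(hd))
        attn = ag.softmax(scores, axis=-1)
        out = ag.matmul(attn, vs)                              # B,h,N,hd
        out = ag.transpose(out, (0, 2, 1, 3))
        out = ag.reshape(out, (b, n, d))
        return self.proj(out)


def _index0(t: Tensor, i: int) -> Tensor:
    """Select index ``i`` along axis 0 (differentiable)."""
    data = t.data[i]

    def backward(g):
        full = np.zeros(t.shape, dtype=DTYPE)
        full[i] = g
        t._accumulate(full)

    return ag._make(data, (t,), backward)


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        self.mods = list(mods)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.mods:
            x = m(x)
        return x


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return ag.relu(x)
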