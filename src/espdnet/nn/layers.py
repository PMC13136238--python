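"""Network building blocks on top of the autograd core."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, conv2d

__all__ = ["Module", "ModuleList", "Parameter", "Conv2d", "Linear", "GroupNorm", "Sequential"]


def Parameter(data) -> Tensor:
    return Tensor(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    """Minimal container: parameters are discovered by attribute traversal."""

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                yield key, value
            elif isinstance(value, Module):
                yield from value.named_parameters(prefix=key + ".")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(prefix=f"{key}.{i}.")
                    elif isinstance(item, Tensor) and item.requires_grad:
                        yield f"{key}.{i}", item

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict:
        return {k: v.data.copy() for k, v in self.named_parameters()}

    def load_state_dict(self, state: dict):
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"missing parameters in state dict: {sorted(missing)[:5]} ...")
        for k, p in own.items():
            arr = np.asarray(state[k], dtype=p.data.dtype)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(Module):
    def __init__(self, modules):
        self.items = list(modules)

    def __iter__(self):
        return iter(self.items)

    def __getitem__(self, i):
        return self.items[i]

    def __len__(self):
        return len(self.items)


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 padding: int | None = None, bias: bool = True, zero_init: bool = False):
        self.kernel = kernel
        self.padding = kernel // 2 if padding is None else padding
        if zero_init:
            w = np.zeros((c_out, c_in, kernel, kernel))
        else:
            fan_in = c_in * kernel * kernel
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, kernel, kernel))
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(c_out)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, padding=self.padding)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 bias: bool = True, zero_init: bool = False):
        w = np.zeros((d_in, d_out)) if zero_init else rng.normal(
            0.0, np.sqrt(2.0 / d_in), size=(d_in, d_out))
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(d_out)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class GroupNorm(Module):
    """Batch-independent normalization, stable at very small batch sizes."""

    def __init__(self, channels: int, groups: int = 4, eps: float = 1e-5):
        while channels % groups:
            groups -= 1
        self.groups = groups
        self.eps = eps
        self.gamma = Parameter(np.ones((1, channels, 1, 1)))
        self.beta = Parameter(np.zeros((1, channels, 1, 1)))

    def forward(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        g = self.groups
        xr = x.reshape(B, g, (C // g) * H * W)
        m = xr.mean(axis=2, keepdims=True)
        centered = xr - m
        var = (centered * centered).mean(axis=2, keepdims=True)
        xn = centered / (var + self.eps).sqrt()
        return xn.reshape(B, C, H, W) * self.gamma + self.beta


class Sequential(Module):
    def __init__(self, *modules):
        self.items = list(modules)

    def forward(self, x):
        for m in self.items:
            x = m(x)
        return x
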