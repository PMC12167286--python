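"""Layers and modules built on the autograd engine."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, conv2d, upsample2x

__all__ = [
    "Module", "Conv2d", "Linear", "GroupNorm", "SiLU", "Sequential",
    "timestep_embedding",
]


class Module:
    """Base class with recursive parameter discovery and a flat state dict."""

    def parameters(self) -> list[Tensor]:
        return [t for _, t in self.named_parameters()]

    def named_parameters(self, prefix: str = ""):
        out = []
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                out.append((key, value))
            elif isinstance(value, Module):
                out.extend(value.named_parameters(prefix=f"{key}."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        out.extend(item.named_parameters(prefix=f"{key}.{i}."))
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        missing = set(params) - set(state)
        extra = set(state) - set(params)
        if missing or extra:
            raise ValueError(f"state dict mismatch: missing={sorted(missing)}, extra={sorted(extra)}")
        for k, v in params.items():
            arr = np.asarray(state[k], dtype=np.float32)
            if arr.shape != v.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {v.data.shape}")
            v.data = arr.copy()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int = 3,
                 stride: int = 1, padding: int | None = None,
                 rng: np.random.Generator | None = None, zero_init: bool = False):
        if padding is None:
            padding = kernel_size // 2
        self.stride = stride
        self.padding = padding
        fan_in = in_channels * kernel_size * kernel_size
        if zero_init:
            w = np.zeros((out_channels, in_channels, kernel_size, kernel_size), np.float32)
        else:
            if rng is None:
                raise ValueError("rng required unless zero_init")
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                           (out_channels, in_channels, kernel_size, kernel_size))
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels, np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator, zero_init: bool = False):
        if zero_init:
            w = np.zeros((in_features, out_features), np.float32)
        else:
            w = rng.normal(0.0, np.sqrt(2.0 / in_features), (in_features, out_features))
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(out_features, np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class GroupNorm(Module):
    """Group normalization over (C/groups, H, W), NCHW input."""

    def __init__(self, channels: int, groups: int = 8, eps: float = 1e-5):
        if channels % groups:
            groups = 1
        self.groups = groups
        self.eps = eps
        self.gamma = Tensor(np.ones(channels, np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        g = self.groups
        xg = x.reshape(n, g, c // g, h, w)
        mu = xg.mean(axis=(2, 3, 4), keepdims=True)
        xc = xg - mu
        var = (xc * xc).mean(axis=(2, 3, 4), keepdims=True)
        norm = xc * (var + self.eps) ** (-0.5)
        norm = norm.reshape(n, c, h, w)
        return norm * self.gamma.reshape(1, c, 1, 1) + self.beta.reshape(1, c, 1, 1)


class SiLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.silu()


class Sequential(Module):
    def __init__(self, *modules: Module):
        self.layers = list(modules)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


def timestep_embedding(t: np.ndarray, dim: int, max_period: float = 10000.0) -> np.ndarray:
    """Sinusoidal embedding of integer timesteps, shape (len(t), dim)."""
    t = np.atleast_1d(np.asarray(t, dtype=np.float64))
    half = dim // 2
    freqs = np.exp(-np.log(max_period) * np.arange(half) / half)
    args = t[:, None] * freqs[None, :]
    emb = np.concatenate([np.cos(args), np.sin(args)], axis=1)
    if dim % 2:
        emb = np.concatenate([emb, np.zeros((len(t), 1))], axis=1)
    return emb.astype(np.float32)


# re-export for convenience of model code
Upsample2x = upsample2x
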