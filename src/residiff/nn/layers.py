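"""Parameterized layers built on the autodiff engine.

Conventions: feature maps are NCHW float32; token tensors are (batch, tokens,
channels).  Every module draws its initial weights from an explicit
``numpy.random.Generator`` so two builds from the same seed are identical.
"""

from __future__ import annotations

import math

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

DTYPE = np.float32


class Module:
    """Base class: parameter discovery by attribute walk."""

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            full = f"{prefix}{name}" if not prefix else f"{prefix}.{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(full)
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}")
                    elif isinstance(item, Tensor) and item.requires_grad:
                        yield f"{full}.{i}", item

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    @property
    def param_count(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        if set(own) != set(state):
            missing = set(own) ^ set(state)
            raise KeyError(f"parameter name mismatch: {sorted(missing)}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=p.data.dtype)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data[...] = arr


def _param(rng: np.random.Generator, shape, fan_in: int, gain: float = 1.0) -> Tensor:
    scale = gain * math.sqrt(2.0 / fan_in)  # He init for SiLU-type activations
    return Tensor(rng.standard_normal(shape).astype(DTYPE) * DTYPE(scale), requires_grad=True)


class Conv2d(Module):
    """Stride-1 convolution with reflection padding (same output size)."""

    def __init__(self, rng, in_ch: int, out_ch: int, kernel: int = 3, gain: float = 1.0):
        self.pad = kernel // 2
        fan_in = in_ch * kernel * kernel
        # small (not zero) gain on block outputs keeps the net near the LR
        # skip at init while leaving every parameter on the gradient path
        self.weight = _param(rng, (out_ch, in_ch, kernel, kernel), fan_in, gain)
        self.bias = Tensor(np.zeros(out_ch, dtype=DTYPE), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return ad.conv2d_valid(ad.reflect_pad2d(x, self.pad), self.weight, self.bias)


class Linear(Module):
    def __init__(self, rng, in_features: int, out_features: int, gain: float = 1.0):
        self.weight = _param(rng, (in_features, out_features), in_features, gain)
        self.bias = Tensor(np.zeros(out_features, dtype=DTYPE), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return (x @ self.weight) + self.bias


class ChannelNorm(Module):
    """Layer normalization over the channel axis of an NCHW map."""

    def __init__(self, channels: int, eps: float = 1e-5):
        self.gain = Tensor(np.ones((1, channels, 1, 1), dtype=DTYPE), requires_grad=True)
        self.shift = Tensor(np.zeros((1, channels, 1, 1), dtype=DTYPE), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=1, keepdims=True)
        centered = x - mu
        var = (centered**2.0).mean(axis=1, keepdims=True)
        inv = (var + self.eps) ** -0.5
        return centered * inv * self.gain + self.shift


class TokenNorm(Module):
    """Layer normalization over the last axis of (batch, tokens, channels)."""

    def __init__(self, dim: int, eps: float = 1e-5):
        self.gain = Tensor(np.ones(dim, dtype=DTYPE), requires_grad=True)
        self.shift = Tensor(np.zeros(dim, dtype=DTYPE), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered**2.0).mean(axis=-1, keepdims=True)
        inv = (var + self.eps) ** -0.5
        return centered * inv * self.gain + self.shift


class ResBlock(Module):
    """conv-norm-SiLU block with timestep scale-and-shift conditioning."""

    def __init__(self, rng, in_ch: int, out_ch: int, time_dim: int):
        self.norm1 = ChannelNorm(in_ch)
        self.conv1 = Conv2d(rng, in_ch, out_ch)
        self.norm2 = ChannelNorm(out_ch)
        self.conv2 = Conv2d(rng, out_ch, out_ch, gain=0.1)
        self.time_scale = Linear(rng, time_dim, out_ch, gain=0.1)
        self.time_shift = Linear(rng, time_dim, out_ch)
        self.skip = Conv2d(rng, in_ch, out_ch, kernel=1) if in_ch != out_ch else None

    def __call__(self, x: Tensor, t_emb: Tensor) -> Tensor:
        h = self.conv1(ad.silu(self.norm1(x)))
        B = t_emb.shape[0]
        scale = self.time_scale(t_emb).reshape((B, -1, 1, 1))
        shift = self.time_shift(t_emb).reshape((B, -1, 1, 1))
        h = self.norm2(h) * (scale + 1.0) + shift
        h = self.conv2(ad.silu(h))
        residual = x if self.skip is None else self.skip(x)
        return h + residual


class WindowAttention(Module):
    """Multi-head self-attention within non-overlapping square windows."""

    def __init__(self, rng, channels: int, window: int, n_heads: int):
        if channels % n_heads:
            raise ValueError(f"channels={channels} not divisible by n_heads={n_heads}")
        self.window = window
        self.n_heads = n_heads
        self.q = Linear(rng, channels, channels)
        self.k = Linear(rng, channels, channels)
        self.v = Linear(rng, channels, channels)
        self.proj = Linear(rng, channels, channels, gain=0.1)

    def _heads(self, x: Tensor, B: int, N: int) -> Tensor:
        d = x.shape[-1] // self.n_heads
        return x.reshape((B, N, self.n_heads, d)).transpose((0, 2, 1, 3))

    def __call__(self, tokens: Tensor) -> Tensor:
        B, N, C = tokens.shape
        d = C // self.n_heads
        q = self._heads(self.q(tokens), B, N)
        k = self._heads(self.k(tokens), B, N)
        v = self._heads(self.v(tokens), B, N)
        attn = ad.softmax((q @ k.transpose((0, 1, 3, 2))) * DTYPE(1.0 / math.sqrt(d)), axis=-1)
        out = (attn @ v).transpose((0, 2, 1, 3)).reshape((B, N, C))
        return self.proj(out)


def window_partition(x: Tensor, window: int) -> tuple[Tensor, tuple[int, int, int, int]]:
    """(B, C, H, W) -> (B * nWindows, window*window, C) token tensor."""
    B, C, H, W = x.shape
    if H % window or W % window:
        raise ValueError(f"spatial size {(H, W)} not divisible by window={window}")
    nh, nw = H // window, W // window
    t = x.reshape((B, C, nh, window, nw, window))
    t = t.transpose((0, 2, 4, 3, 5, 1))  # B, nh, nw, win, win, C
    return t.reshape((B * nh * nw, window * window, C)), (B, C, H, W)


def window_merge(tokens: Tensor, window: int, shape: tuple[int, int, int, int]) -> Tensor:
    B, C, H, W = shape
    nh, nw = H // window, W // window
    t = tokens.reshape((B, nh, nw, window, window, C))
    t = t.transpose((0, 5, 1, 3, 2, 4))  # B, C, nh, win, nw, win
    return t.reshape((B, C, H, W))


class SwinBlock(Module):
    """norm -> windowed MSA -> norm -> MLP, each with a residual addition."""

    def __init__(self, rng, channels: int, window: int, n_heads: int, mlp_ratio: int = 2):
        self.window = window
        self.norm1 = TokenNorm(channels)
        self.attn = WindowAttention(rng, channels, window, n_heads)
        self.norm2 = TokenNorm(channels)
        self.fc1 = Linear(rng, channels, mlp_ratio * channels)
        self.fc2 = Linear(rng, mlp_ratio * channels, channels, gain=0.1)

    def __call__(self, x: Tensor) -> Tensor:
        tokens, shape = window_partition(x, self.window)
        tokens = tokens + self.attn(self.norm1(tokens))
        tokens = tokens + self.fc2(ad.silu(self.fc1(self.norm2(tokens))))
        return window_merge(tokens, self.window, shape)


def sinusoidal_embedding(t: int | np.ndarray, dim: int, max_period: float = 10000.0) -> np.ndarray:
    """Interleaved sin/cos positional encoding of timestep(s).

    Returns shape (dim,) for a scalar t, (len(t), dim) for an array.
    """
    if dim % 2:
        raise ValueError(f"embedding dim must be even, got {dim}")
    t_arr = np.atleast_1d(np.asarray(t, dtype=np.float64))
    half = dim // 2
    freqs = max_period ** (-np.arange(half) / half)
    angles = t_arr[:, None] * freqs[None, :]
    emb = np.empty((t_arr.shape[0], dim), dtype=DTYPE)
    emb[:, 0::2] = np.sin(angles)
    emb[:, 1::2] = np.cos(angles)
    return emb[0] if np.isscalar(t) or np.ndim(t) == 0 else emb
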