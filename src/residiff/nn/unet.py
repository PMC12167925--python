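"""U-shaped denoiser g(x_t, x_lr, t) -> x0_hat with windowed self-attention.

The network concatenates the diffused image and the LR reference at the stem,
injects a sinusoidal timestep embedding into every residual block, and runs a
down/up path with skip connections.  Window-attention blocks (layer-norm ->
windowed multi-head self-attention -> layer-norm -> MLP, residual additions)
replace conventional attention at the two coarsest resolutions; the ablation
variant drops them.  A global skip from the LR image means the network learns
the HR correction on top of the LR input.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .layers import (
    DTYPE,
    ChannelNorm,
    Conv2d,
    Linear,
    Module,
    ResBlock,
    SwinBlock,
    sinusoidal_embedding,
)

__all__ = ["DenoiserConfig", "UNetDenoiser", "build_denoiser", "timestep_embedding", "TINY", "PAPER_SCALE"]


class DenoiserConfigError(ValueError):
    pass


@dataclass(frozen=True)
class DenoiserConfig:
    """Architecture hyper-parameters.

    Input spatial size must be divisible by ``2**depth``, and by
    ``window_size`` at every attended level (checked at call time).
    """

    base_width: int = 16
    depth: int = 2
    window_size: int = 4
    use_swin: bool = True
    time_embed_dim: int = 64
    n_heads: int = 4

    def widths(self) -> list[int]:
        return [self.base_width * 2**i for i in range(self.depth + 1)]

    def to_dict(self) -> dict:
        return asdict(self)


# presets: "tiny" trains on CPU in minutes; "paper_scale" mirrors common
# diffusion U-net sizing (64 base channels, 4 levels) for GPU-class runs
TINY = DenoiserConfig(base_width=16, depth=2, window_size=4, time_embed_dim=64)
PAPER_SCALE = DenoiserConfig(base_width=64, depth=4, window_size=8, time_embed_dim=256)


def timestep_embedding(t: int | np.ndarray, dim: int) -> np.ndarray:
    """Sinusoidal embedding of the diffusion step indicator."""
    return sinusoidal_embedding(t, dim)


class UNetDenoiser(Module):
    """Encoder-decoder denoiser with timestep conditioning."""

    def __init__(self, cfg: DenoiserConfig, seed: int = 0):
        if cfg.time_embed_dim % 2:
            raise DenoiserConfigError("time_embed_dim must be even")
        if cfg.base_width % cfg.n_heads:
            raise DenoiserConfigError(
                f"base_width={cfg.base_width} must be divisible by n_heads={cfg.n_heads}"
            )
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        widths = cfg.widths()
        td = cfg.time_embed_dim

        self.time_fc1 = Linear(rng, td, td)
        self.time_fc2 = Linear(rng, td, td)

        self.stem = Conv2d(rng, 2, widths[0])
        self.down_blocks = [
            ResBlock(rng, widths[i], widths[i + 1], td) for i in range(cfg.depth)
        ]
        # attended levels: the two coarsest resolutions of the pyramid
        attn_levels = {cfg.depth, cfg.depth - 1} if cfg.use_swin else set()
        self.down_attn = [
            SwinBlock(rng, widths[i + 1], cfg.window_size, cfg.n_heads)
            if (i + 1) in attn_levels
            else None
            for i in range(cfg.depth)
        ]
        self.mid = ResBlock(rng, widths[-1], widths[-1], td)
        self.mid_attn = (
            SwinBlock(rng, widths[-1], cfg.window_size, cfg.n_heads) if cfg.use_swin else None
        )
        self.up_convs = [
            Conv2d(rng, widths[i + 1], widths[i]) for i in reversed(range(cfg.depth))
        ]
        self.up_blocks = [
            ResBlock(rng, 2 * widths[i], widths[i], td) for i in reversed(range(cfg.depth))
        ]
        self.head_norm = ChannelNorm(widths[0])
        self.head = Conv2d(rng, widths[0], 1, gain=0.1)

    # -- core forward ------------------------------------------------------
    def _check_size(self, H: int, W: int) -> None:
        cfg = self.cfg
        f = 2**cfg.depth
        if H % f or W % f:
            raise DenoiserConfigError(
                f"input size {(H, W)} must be divisible by 2**depth = {f}"
            )
        if cfg.use_swin:
            for level in (cfg.depth - 1, cfg.depth):
                h, w = H // 2**level, W // 2**level
                if h % cfg.window_size or w % cfg.window_size:
                    raise DenoiserConfigError(
                        f"attended level {level} size {(h, w)} must be divisible by "
                        f"window_size = {cfg.window_size}"
                    )

    def forward(self, x_t: Tensor, x_lr: Tensor, t: np.ndarray) -> Tensor:
        """Batched graph forward: x_t, x_lr are (B, 1, H, W); t is (B,) ints."""
        B, _, H, W = x_t.shape
        self._check_size(H, W)
        emb = Tensor(sinusoidal_embedding(np.asarray(t), self.cfg.time_embed_dim))
        t_emb = self.time_fc2(ad.silu(self.time_fc1(emb)))

        h = self.stem(ad.concat([x_t, x_lr], axis=1))
        skips = []
        for block, attn in zip(self.down_blocks, self.down_attn):
            skips.append(h)
            h = block(ad.avg_pool2d(h, 2), t_emb)
            if attn is not None:
                h = attn(h)
        h = self.mid(h, t_emb)
        if self.mid_attn is not None:
            h = self.mid_attn(h)
        for conv, block, skip in zip(self.up_convs, self.up_blocks, reversed(skips)):
            h = conv(ad.upsample_nearest2d(h, 2))
            h = block(ad.concat([h, skip], axis=1), t_emb)
        out = self.head(ad.silu(self.head_norm(h)))
        return out + x_lr  # global LR skip: the net predicts the HR correction

    # -- inference contract --------------------------------------------------
    def predict(self, x_t: np.ndarray, x_lr: np.ndarray, t: int) -> np.ndarray:
        """Single-slice clean-image estimate; numpy in, numpy out, no graph."""
        xt = Tensor(np.asarray(x_t, dtype=DTYPE)[None, None])
        xl = Tensor(np.asarray(x_lr, dtype=DTYPE)[None, None])
        out = self.forward(xt, xl, np.array([t]))
        return out.data[0, 0]


def build_denoiser(cfg: DenoiserConfig, seed: int = 0) -> UNetDenoiser:
    """Construct a seeded denoiser satisfying the predict contract."""
    return UNetDenoiser(cfg, seed=seed)
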