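"""Training loop for the denoiser: composite loss, warm-up + cosine learning
rate, seeded per-step corruption, and resumable checkpoints.

Each step draws an independent uniform timestep per sample, corrupts the HR
slice with the closed-form forward marginal, asks the network for a clean
estimate, and minimizes ``lam * MSE(x0_hat, x_hr) + perceptual(x0_hat, x_hr)``
with an adaptive-moment optimizer.  All randomness derives from
``(seed, step)`` substreams, so a run is bit-reproducible and a resumed run
continues identically.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .nn.autodiff import Tensor
from .nn.layers import DTYPE
from .nn.optim import make_optimizer
from .nn.unet import DenoiserConfig, UNetDenoiser, build_denoiser
from .schedule import PairedSample, ResidualShiftSchedule, build_schedule

__all__ = ["LossConfig", "TrainConfig", "training_loss", "lr_at_step", "train_step", "fit", "save_checkpoint", "load_checkpoint"]

PerceptualFn = Callable[[Tensor, Tensor], Tensor]


@dataclass(frozen=True)
class LossConfig:
    """Composite objective: lam-weighted fidelity plus perceptual distance."""

    lam: float = 10.0
    perceptual: PerceptualFn | None = None

    def __post_init__(self):
        if self.lam <= 0:
            raise ValueError("lam must be > 0")


@dataclass(frozen=True)
class TrainConfig:
    total_steps: int = 1000
    batch_size: int = 16
    lr_init: float = 1e-3
    warmup_steps: int = 100
    seed: int = 0
    checkpoint_every: int = 0  # 0 disables periodic checkpoints
    optimizer: str = "radam"
    grad_clip: float = 0.0  # 0 disables clipping

    def __post_init__(self):
        if self.total_steps < 0 or self.batch_size < 1 or self.lr_init <= 0:
            raise ValueError("counts must be positive and lr_init > 0")
        if self.total_steps > 0 and self.warmup_steps >= self.total_steps:
            raise ValueError(
                f"warmup_steps={self.warmup_steps} must be < total_steps={self.total_steps}"
            )


# tiny CPU preset: short warm-up and a deliberately larger lr than the
# full-scale setting, which is sized for hundred-thousand-step runs
TINY_TRAIN = TrainConfig(total_steps=1000, batch_size=16, lr_init=1e-3, warmup_steps=100)
# full-scale preset: published batch size, lr from the published range,
# 5000-step warm-up, run lengths of order 1e5 steps
PAPER_TRAIN = TrainConfig(
    total_steps=182_000, batch_size=16, lr_init=5e-5, warmup_steps=5000,
    checkpoint_every=10_000,
)


def training_loss(x0_hat: Tensor, x_hr: Tensor, cfg: LossConfig = LossConfig()) -> Tensor:
    """lam * mean((x0_hat - x_hr)^2) + perceptual(x0_hat, x_hr)."""
    if x0_hat.shape != x_hr.shape:
        raise ValueError(f"shape mismatch: {x0_hat.shape} vs {x_hr.shape}")
    loss = ((x0_hat - x_hr) ** 2.0).mean() * cfg.lam
    if cfg.perceptual is not None:
        loss = loss + cfg.perceptual(x0_hat, x_hr)
    return loss


def lr_at_step(step: int, cfg: TrainConfig) -> float:
    """Linear ramp to lr_init over the warm-up, then half-cosine decay to 0."""
    if not 0 <= step <= cfg.total_steps:
        raise ValueError(f"step {step} outside [0, {cfg.total_steps}]")
    if step < cfg.warmup_steps:
        return cfg.lr_init * step / cfg.warmup_steps
    frac = (step - cfg.warmup_steps) / (cfg.total_steps - cfg.warmup_steps)
    return cfg.lr_init * 0.5 * (1.0 + math.cos(math.pi * frac))


def _step_rng(seed: int, step: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(step,)))


class NonFiniteLossError(RuntimeError):
    pass


def train_step(
    batch: Sequence[PairedSample],
    denoiser: UNetDenoiser,
    sched: ResidualShiftSchedule,
    loss_cfg: LossConfig,
    optimizer,
    rng: np.random.Generator,
    noise_scale: float = 1.0,
) -> float:
    """One gradient step on a batch; returns the scalar loss.

    ``noise_scale=0`` suppresses the corruption noise (test hook).
    """
    if len(batch) == 0:
        raise ValueError("empty batch")
    t_draws = rng.integers(1, sched.T + 1, size=len(batch))
    x_hr = np.stack([s.x_hr for s in batch])[:, None].astype(DTYPE)
    x_lr = np.stack([s.x_lr for s in batch])[:, None].astype(DTYPE)
    betas = sched.beta[t_draws].astype(DTYPE)[:, None, None, None]
    noise = rng.standard_normal(x_hr.shape).astype(DTYPE) * DTYPE(noise_scale)
    x_t = x_hr + betas * (x_lr - x_hr) + DTYPE(sched.gamma) * np.sqrt(betas) * noise

    x0_hat = denoiser.forward(Tensor(x_t), Tensor(x_lr), t_draws)
    loss = training_loss(x0_hat, Tensor(x_hr), loss_cfg)
    value = loss.item()
    if not math.isfinite(value):
        fid = float(np.mean((x0_hat.data - x_hr) ** 2))
        raise NonFiniteLossError(
            f"non-finite loss {value}; t draws {t_draws.tolist()}, fidelity term {fid}"
        )
    optimizer.zero_grad()
    loss.backward()
    if getattr(optimizer, "grad_clip", 0.0):
        _clip_gradients(optimizer.params, optimizer.grad_clip)
    optimizer.step()
    return value


def _clip_gradients(params, max_norm: float) -> None:
    total = math.sqrt(sum(float((p.grad**2).sum()) for p in params if p.grad is not None))
    if total > max_norm:
        scale = max_norm / (total + 1e-12)
        for p in params:
            if p.grad is not None:
                p.grad *= scale


def fit(
    dataset: Sequence[PairedSample],
    denoiser: UNetDenoiser,
    sched: ResidualShiftSchedule,
    loss_cfg: LossConfig = LossConfig(),
    train_cfg: TrainConfig = TINY_TRAIN,
    checkpoint_dir: str | Path | None = None,
    resume_from: str | Path | None = None,
    log_every: int = 0,
) -> tuple[UNetDenoiser, list[float]]:
    """Run the training loop; returns the trained denoiser and the loss trace.

    With ``resume_from`` the loop continues from the stored step with the same
    per-step randomness it would have used uninterrupted.
    """
    optimizer = make_optimizer(
        train_cfg.optimizer, denoiser.parameters(), lr=train_cfg.lr_init
    )
    optimizer.grad_clip = train_cfg.grad_clip
    start_step = 0
    trace: list[float] = []
    if resume_from is not None:
        start_step, trace = load_checkpoint(resume_from, denoiser, optimizer)

    for step in range(start_step, train_cfg.total_steps):
        # evaluate the ramp mid-step so neither endpoint step is wasted
        optimizer.lr = lr_at_step(step, train_cfg) if step >= train_cfg.warmup_steps else (
            train_cfg.lr_init * (step + 1) / max(train_cfg.warmup_steps, 1)
        )
        rng = _step_rng(train_cfg.seed, step)
        idx = rng.choice(len(dataset), size=min(train_cfg.batch_size, len(dataset)), replace=False)
        batch = [dataset[i] for i in idx]
        value = train_step(batch, denoiser, sched, loss_cfg, optimizer, rng)
        trace.append(value)
        if log_every and (step + 1) % log_every == 0:
            print(f"step {step + 1}/{train_cfg.total_steps} loss {value:.5f} lr {optimizer.lr:.2e}")
        if (
            checkpoint_dir is not None
            and train_cfg.checkpoint_every
            and (step + 1) % train_cfg.checkpoint_every == 0
        ):
            save_checkpoint(
                Path(checkpoint_dir) / f"ckpt_{step + 1:06d}.npz",
                denoiser, optimizer, sched, step + 1, trace,
            )
    if checkpoint_dir is not None:
        save_checkpoint(
            Path(checkpoint_dir) / "ckpt_final.npz",
            denoiser, optimizer, sched, train_cfg.total_steps, trace,
        )
    return denoiser, trace


# -- checkpointing ----------------------------------------------------------


def save_checkpoint(
    path: str | Path,
    denoiser: UNetDenoiser,
    optimizer,
    sched: ResidualShiftSchedule,
    step: int,
    trace: Sequence[float],
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {f"param:{k}": v for k, v in denoiser.state_dict().items()}
    arrays.update({f"opt:{k}": v for k, v in optimizer.state_arrays().items()})
    meta = {
        "step": step,
        "config": denoiser.cfg.to_dict(),
        "schedule": sched.dumps(),
        "trace": list(map(float, trace)),
    }
    try:
        np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)
    except OSError as exc:
        raise OSError(f"checkpoint write failed at {path}: {exc}") from exc


def load_checkpoint(
    path: str | Path,
    denoiser: UNetDenoiser | None = None,
    optimizer=None,
) -> tuple[int, list[float]]:
    """Restore parameters (and optimizer state) in place; returns (step, trace)."""
    with np.load(Path(path)) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        if denoiser is not None:
            if meta["config"] != denoiser.cfg.to_dict():
                raise ValueError("checkpoint architecture differs from the given denoiser")
            denoiser.load_state_dict(
                {k[len("param:") :]: data[k] for k in data.files if k.startswith("param:")}
            )
        if optimizer is not None:
            optimizer.load_state_arrays(
                {k[len("opt:") :]: data[k] for k in data.files if k.startswith("opt:")}
            )
    return int(meta["step"]), list(meta["trace"])


def checkpoint_denoiser(path: str | Path) -> tuple[UNetDenoiser, ResidualShiftSchedule]:
    """Rebuild a denoiser + schedule directly from a checkpoint file."""
    with np.load(Path(path)) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        cfg = DenoiserConfig(**meta["config"])
        model = build_denoiser(cfg, seed=0)
        model.load_state_dict(
            {k[len("param:") :]: data[k] for k in data.files if k.startswith("param:")}
        )
    sched = ResidualShiftSchedule.loads(meta["schedule"])
    return model, sched
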