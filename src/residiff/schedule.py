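"""Residual-shifting diffusion: noise schedule, forward process, posterior, sampler.

The forward process moves a high-resolution slice ``x0`` toward its
low-resolution counterpart by accumulating fractions of the residual
``e0 = x_lr - x0`` while injecting Gaussian noise::

    x_t = x0 + beta_t * e0 + gamma * sqrt(beta_t) * eps,   eps ~ N(0, I)

``beta_t`` grows from ``beta_1 = (kappa/gamma)^2`` (nearly clean) to
``beta_T`` close to 1 (nearly the LR image plus noise) along a geometric
schedule whose growth rate is controlled by the exponent ``p``.  The reverse
process walks back down the same ladder using a learned estimate ``x0_hat``
of the clean image; because the residual cancels algebraically in the
posterior, sampling needs only ``x_t`` and ``x0_hat`` and can therefore skip
steps — this is what makes 4-step sampling of a 15-step schedule exact in
the noise-free limit.

Everything in this module is pure (numpy in/out, no learning) and is
exercised against brute-force simulation and discretized-Bayes oracles in
the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "ResidualShiftSchedule",
    "PairedSample",
    "DiffusionState",
    "PosteriorParams",
    "build_schedule",
    "default_step_grid",
    "forward_step",
    "forward_marginal",
    "posterior_params",
    "init_sample",
    "reverse_step",
    "sample",
]

IMAGE_DTYPE = np.float32  # image arithmetic in single precision; schedules in double


class ScheduleConfigError(ValueError):
    """Raised when schedule hyper-parameters are outside their valid ranges."""


@dataclass(frozen=True)
class ResidualShiftSchedule:
    """Cumulative shift fractions ``beta`` and their increments ``alpha``.

    ``beta`` has length ``T + 1`` with the sentinel ``beta[0] = 0`` prepended,
    so ``beta[t]`` is the fraction of the residual accumulated after forward
    step ``t``.  ``alpha`` has length ``T`` with ``alpha[t-1] = beta[t] -
    beta[t-1]``.
    """

    T: int
    p: float
    gamma: float
    kappa: float
    beta_T: float
    beta: np.ndarray = field(repr=False)
    alpha: np.ndarray = field(repr=False)

    @property
    def beta_1(self) -> float:
        return float(self.beta[1])

    def alpha_at(self, t: int) -> float:
        """Increment beta_t - beta_{t-1} for 1-based step t."""
        if not 1 <= t <= self.T:
            raise IndexError(f"step t={t} outside [1, {self.T}]")
        return float(self.alpha[t - 1])

    def beta_at(self, t: int) -> float:
        if not 0 <= t <= self.T:
            raise IndexError(f"step t={t} outside [0, {self.T}]")
        return float(self.beta[t])

    def dumps(self) -> str:
        """Plain-text key-value manifest (reproducibility record)."""
        lines = [
            f"T: {self.T}",
            f"p: {self.p!r}",
            f"gamma: {self.gamma!r}",
            f"kappa: {self.kappa!r}",
            f"beta_T: {self.beta_T!r}",
            "beta: " + " ".join(repr(float(b)) for b in self.beta),
        ]
        return "\n".join(lines) + "\n"

    @classmethod
    def loads(cls, text: str) -> "ResidualShiftSchedule":
        kv = {}
        for line in text.strip().splitlines():
            key, _, value = line.partition(":")
            kv[key.strip()] = value.strip()
        sched = build_schedule(
            T=int(kv["T"]),
            p=float(kv["p"]),
            gamma=float(kv["gamma"]),
            kappa=float(kv["kappa"]),
            beta_T=float(kv["beta_T"]),
        )
        stored = np.array([float(x) for x in kv["beta"].split()])
        if not np.allclose(stored, sched.beta, rtol=0, atol=1e-15):
            raise ValueError("stored beta sequence disagrees with rebuilt schedule")
        return sched


@dataclass
class PairedSample:
    """Aligned HR/LR slice pair on a common grid, intensities in [0, 1]."""

    x_hr: np.ndarray
    x_lr: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.x_hr = np.asarray(self.x_hr, dtype=IMAGE_DTYPE)
        self.x_lr = np.asarray(self.x_lr, dtype=IMAGE_DTYPE)
        if self.x_hr.shape != self.x_lr.shape:
            raise ValueError(
                f"HR/LR shape mismatch: {self.x_hr.shape} vs {self.x_lr.shape}"
            )
        if not (np.isfinite(self.x_hr).all() and np.isfinite(self.x_lr).all()):
            raise ValueError("non-finite intensities in paired sample")

    @property
    def e0(self) -> np.ndarray:
        """Residual shift driving the forward process."""
        return self.x_lr - self.x_hr


@dataclass
class DiffusionState:
    """Image at a point along the diffusion trajectory."""

    x_t: np.ndarray
    t: int


@dataclass
class PosteriorParams:
    """Gaussian posterior q(x_lo | x_hi, x0): image-shaped mean, scalar variance."""

    mean: np.ndarray
    var: float


def build_schedule(
    T: int = 15,
    p: float = 0.3,
    gamma: float = 2.0,
    kappa: float = 0.04,
    beta_T: float = 0.9999,
) -> ResidualShiftSchedule:
    """Construct the geometric shift schedule.

    ``sqrt(beta_t)`` interpolates log-linearly in ``((t-1)/(T-1))^p`` between
    ``sqrt(beta_1)`` and ``sqrt(beta_T)``, with ``beta_1 = (kappa/gamma)^2``
    pinning the first step to a nearly-clean image and ``beta_T`` pinning the
    last to (almost) the LR image.  Smaller ``p`` front-loads the shift.
    """
    if T < 2:
        raise ScheduleConfigError(f"T must be >= 2, got T={T}")
    if p <= 0:
        raise ScheduleConfigError(f"p must be > 0, got p={p}")
    if gamma <= 0:
        raise ScheduleConfigError(f"gamma must be > 0, got gamma={gamma}")
    beta_1 = (kappa / gamma) ** 2
    if not 0.0 < beta_1 < beta_T:
        raise ScheduleConfigError(
            f"kappa implies beta_1={beta_1:g}, which must lie in (0, beta_T={beta_T:g})"
        )
    if not beta_T <= 1.0:
        raise ScheduleConfigError(f"beta_T must be <= 1, got beta_T={beta_T}")

    t = np.arange(1, T + 1, dtype=np.float64)
    log_ratio = math.log(math.sqrt(beta_T / beta_1))
    sqrt_beta = math.sqrt(beta_1) * np.exp(((t - 1) / (T - 1)) ** p * log_ratio)
    beta = sqrt_beta**2
    beta[0] = beta_1  # exact endpoints
    beta[-1] = beta_T
    beta = np.concatenate([[0.0], beta])
    alpha = np.diff(beta)
    if np.any(alpha <= 0):
        raise ScheduleConfigError("schedule is not strictly increasing")
    return ResidualShiftSchedule(
        T=T, p=p, gamma=gamma, kappa=kappa, beta_T=beta_T, beta=beta, alpha=alpha
    )


def default_step_grid(T: int, n_steps: int) -> list[int]:
    """Evenly spaced sampling grid from T down to 0, with ``n_steps`` denoiser calls.

    For T=15, n_steps=4 this gives [15, 11, 7, 3, 0]; for n_steps=T the full
    per-step grid [T, T-1, ..., 0].
    """
    if not 1 <= n_steps <= T:
        raise ValueError(f"n_steps must be in [1, T={T}], got {n_steps}")
    stride = math.ceil(T / n_steps)
    grid = [max(T - k * stride, 0) for k in range(n_steps)]
    grid.append(0)
    # drop duplicates that can appear when stride*n_steps > T
    out = [grid[0]]
    for g in grid[1:]:
        if g < out[-1]:
            out.append(g)
    return out


def _check_t(t: int, T: int) -> None:
    if not 1 <= t <= T:
        raise IndexError(f"step t={t} outside [1, {T}]")


def forward_step(
    x_prev: np.ndarray,
    e0: np.ndarray,
    sched: ResidualShiftSchedule,
    t: int,
    noise: np.ndarray,
) -> np.ndarray:
    """One forward transition: x_t = x_{t-1} + alpha_t e0 + gamma sqrt(alpha_t) eps."""
    _check_t(t, sched.T)
    a = sched.alpha_at(t)
    return (x_prev + a * e0 + sched.gamma * math.sqrt(a) * noise).astype(
        np.result_type(x_prev, IMAGE_DTYPE)
    )


def forward_marginal(
    sample: PairedSample,
    sched: ResidualShiftSchedule,
    t: int,
    noise: np.ndarray,
) -> DiffusionState:
    """Closed-form corruption: x_t = x0 + beta_t e0 + gamma sqrt(beta_t) eps."""
    _check_t(t, sched.T)
    b = sched.beta_at(t)
    x_t = sample.x_hr + b * sample.e0 + sched.gamma * math.sqrt(b) * noise
    return DiffusionState(x_t=x_t.astype(IMAGE_DTYPE), t=t)


def posterior_params(
    x_t: np.ndarray,
    x0_hat: np.ndarray,
    sched: ResidualShiftSchedule,
    t_hi: int,
    t_lo: int,
) -> PosteriorParams:
    """Gaussian posterior of the state at ``t_lo`` given the state at ``t_hi``.

    For adjacent steps this is the textbook product-of-Gaussians posterior
    (mean ``(beta_{t-1}/beta_t) x_t + (alpha_t/beta_t) x0``, variance
    ``gamma^2 alpha_t beta_{t-1}/beta_t``); for non-adjacent steps the same
    algebra applies with ``alpha`` replaced by ``beta_hi - beta_lo``, because
    the residual term cancels between the two marginals.  The returned
    variance is exactly 0 when ``t_lo`` is 0.
    """
    if not 0 <= t_lo < t_hi <= sched.T:
        raise ValueError(f"require 0 <= t_lo < t_hi <= T, got t_lo={t_lo}, t_hi={t_hi}")
    b_hi = sched.beta_at(t_hi)
    b_lo = sched.beta_at(t_lo)
    w_x = b_lo / b_hi
    w_0 = (b_hi - b_lo) / b_hi
    mean = (w_x * x_t + w_0 * x0_hat).astype(np.result_type(x_t, IMAGE_DTYPE))
    var = sched.gamma**2 * (b_hi - b_lo) * b_lo / b_hi
    return PosteriorParams(mean=mean, var=float(var))


def init_sample(
    x_lr: np.ndarray,
    sched: ResidualShiftSchedule,
    noise: np.ndarray,
) -> DiffusionState:
    """Initialize the reverse process at t = T around the LR image."""
    x_T = x_lr + sched.gamma * math.sqrt(sched.beta_T) * noise
    return DiffusionState(x_t=np.asarray(x_T, dtype=IMAGE_DTYPE), t=sched.T)


def reverse_step(
    state: DiffusionState,
    x0_hat: np.ndarray,
    sched: ResidualShiftSchedule,
    t_lo: int,
    noise: np.ndarray,
) -> DiffusionState:
    """Draw the state at ``t_lo`` from the posterior given the state at ``state.t``."""
    if not state.t > t_lo >= 0:
        raise ValueError(f"require state.t > t_lo >= 0, got {state.t} -> {t_lo}")
    post = posterior_params(state.x_t, x0_hat, sched, t_hi=state.t, t_lo=t_lo)
    x_lo = post.mean + math.sqrt(post.var) * noise
    return DiffusionState(x_t=x_lo.astype(IMAGE_DTYPE), t=t_lo)


def _step_rng(seed: int, t: int) -> np.random.Generator:
    # independent substream per visited timestep, all keyed by one seed
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(t,)))


def sample(
    x_lr: np.ndarray,
    denoiser: Callable[[np.ndarray, np.ndarray, int], np.ndarray],
    sched: ResidualShiftSchedule,
    step_grid: Sequence[int] | None = None,
    seed: int = 0,
    stochastic: bool = True,
) -> np.ndarray:
    """Run the reverse process from the LR image to a restored HR estimate.

    ``denoiser(x_t, x_lr, t)`` returns the clean-image estimate x0_hat.
    ``step_grid`` must start at T and end at 0 and be strictly decreasing;
    by default it is the 4-call evenly spaced grid.  With ``stochastic=False``
    every noise draw is suppressed (used by the exact-recovery oracle tests).
    Identical seeds give bit-identical outputs.
    """
    if step_grid is None:
        step_grid = default_step_grid(sched.T, min(4, sched.T))
    step_grid = list(step_grid)
    if step_grid[0] != sched.T or step_grid[-1] != 0:
        raise ScheduleConfigError(
            f"step_grid must start at T={sched.T} and end at 0, got {step_grid}"
        )
    if any(b >= a for a, b in zip(step_grid, step_grid[1:])):
        raise ScheduleConfigError(f"step_grid must be strictly decreasing: {step_grid}")

    x_lr = np.asarray(x_lr, dtype=IMAGE_DTYPE)

    def draw(t: int) -> np.ndarray:
        if not stochastic:
            return np.zeros_like(x_lr)
        return _step_rng(seed, t).standard_normal(x_lr.shape).astype(IMAGE_DTYPE)

    state = init_sample(x_lr, sched, draw(sched.T + 1))
    for t_lo in step_grid[1:]:
        x0_hat = np.asarray(denoiser(state.x_t, x_lr, state.t), dtype=IMAGE_DTYPE)
        state = reverse_step(state, x0_hat, sched, t_lo, draw(t_lo))
    return state.x_t
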