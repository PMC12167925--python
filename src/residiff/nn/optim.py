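"""Adaptive-moment optimizers (Adam and Rectified Adam) for Tensor parameters."""

from __future__ import annotations

import math

import numpy as np

from .autodiff import Tensor

__all__ = ["Adam", "RAdam", "make_optimizer"]


class Adam:
    """Standard Adam with bias correction."""

    name = "adam"

    def __init__(self, params: list[Tensor], lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.step_count = 0
        self.m = [np.zeros_like(p.data, dtype=np.float32) for p in self.params]
        self.v = [np.zeros_like(p.data, dtype=np.float32) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def _update(self, p: Tensor, m: np.ndarray, v: np.ndarray) -> None:
        t = self.step_count
        mhat = m / (1 - self.beta1**t)
        vhat = v / (1 - self.beta2**t)
        p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.data.dtype)

    def step(self) -> None:
        self.step_count += 1
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad.astype(np.float32)
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            self._update(p, m, v)

    # -- checkpoint support -------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {"step_count": np.array(self.step_count)}
        for i, (m, v) in enumerate(zip(self.m, self.v)):
            out[f"m{i}"] = m
            out[f"v{i}"] = v
        return out

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        self.step_count = int(state["step_count"])
        for i in range(len(self.params)):
            self.m[i][...] = state[f"m{i}"]
            self.v[i][...] = state[f"v{i}"]


class RAdam(Adam):
    """Rectified Adam: variance rectification replaces fixed warm-up.

    Falls back to an un-adapted momentum step while the second-moment
    estimate is too short to be trusted.
    """

    name = "radam"

    def _update(self, p: Tensor, m: np.ndarray, v: np.ndarray) -> None:
        t = self.step_count
        mhat = m / (1 - self.beta1**t)
        rho_inf = 2 / (1 - self.beta2) - 1
        rho = rho_inf - 2 * t * self.beta2**t / (1 - self.beta2**t)
        if rho > 4:
            vhat = np.sqrt(v / (1 - self.beta2**t))
            r = math.sqrt(
                ((rho - 4) * (rho - 2) * rho_inf) / ((rho_inf - 4) * (rho_inf - 2) * rho)
            )
            p.data -= (self.lr * r * mhat / (vhat + self.eps)).astype(p.data.dtype)
        else:
            p.data -= (self.lr * mhat).astype(p.data.dtype)


def make_optimizer(kind: str, params: list[Tensor], lr: float) -> Adam:
    kinds = {"adam": Adam, "radam": RAdam}
    if kind not in kinds:
        raise ValueError(f"unknown optimizer {kind!r}; choose from {sorted(kinds)}")
    return kinds[kind](params, lr=lr)
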