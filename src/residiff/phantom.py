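"""Seeded synthetic MRI-like phantoms: the test bed replacing clinical data.

Each phantom is a single-channel 2-D slice emulating a skull-stripped,
background-masked acquisition: nested soft-tissue ellipses (piecewise-smooth
anatomy), thin curvilinear features (vessel/septum-like, 1-2 px), small
high-contrast lesions, an optional smooth bias field, and additive Gaussian
noise.  Background outside the outer ellipse is exactly zero and intensities
live in [0, 1].  The LR counterpart comes from the degradation operator, with
the mask re-applied so the residual e0 = x_lr - x_hr vanishes on background.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .degrade import DegradeSpec, degrade
from .schedule import PairedSample

__all__ = ["PhantomSpec", "make_phantom", "make_dataset"]


@dataclass(frozen=True)
class PhantomSpec:
    size: int = 64
    n_structures: int = 4
    lesion_count: int = 3
    lesion_radius_px: float = 2.0
    curvilinear_count: int = 3
    noise_sigma: float = 0.01
    bias_field: bool = True
    factors: tuple[float, float] = (4.0, 4.0)
    seed: int = 0

    def __post_init__(self):
        if self.size < 8:
            raise ValueError("size must be >= 8")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


def _ellipse_mask(size, cy, cx, ry, rx, theta) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    y, x = yy - cy, xx - cx
    c, s = np.cos(theta), np.sin(theta)
    u = c * x + s * y
    v = -s * x + c * y
    return (u / rx) ** 2 + (v / ry) ** 2 <= 1.0


def make_phantom(spec: PhantomSpec) -> PairedSample:
    """Generate one HR slice and its degraded LR pair; deterministic in seed."""
    rng = np.random.default_rng(spec.seed)
    n = spec.size
    img = np.zeros((n, n), dtype=np.float64)

    # nested anatomy: outer ellipse defines the foreground mask
    cy, cx = n / 2 + rng.uniform(-n * 0.03, n * 0.03, 2)
    ry, rx = n * rng.uniform(0.38, 0.45), n * rng.uniform(0.32, 0.42)
    theta0 = rng.uniform(0, np.pi)
    mask = _ellipse_mask(n, cy, cx, ry, rx, theta0)
    img[mask] = rng.uniform(0.25, 0.45)
    shrink = 1.0
    for _ in range(max(spec.n_structures - 1, 0)):
        shrink *= rng.uniform(0.55, 0.8)
        dy, dx = rng.uniform(-n * 0.05, n * 0.05, 2)
        inner = _ellipse_mask(
            n, cy + dy, cx + dx, ry * shrink, rx * shrink, theta0 + rng.uniform(-0.5, 0.5)
        )
        img[inner & mask] = rng.uniform(0.3, 0.9)

    # thin curvilinear features: quadratic arcs 1-2 px wide
    for _ in range(spec.curvilinear_count):
        t = np.linspace(0, 1, 4 * n)
        p0, p1, p2 = (rng.uniform(0.15, 0.85, 2) * n for _ in range(3))
        pts = ((1 - t) ** 2)[:, None] * p0 + (2 * t * (1 - t))[:, None] * p1 + (t**2)[:, None] * p2
        width = rng.integers(1, 3)
        level = rng.uniform(0.6, 1.0)
        for py, px in pts:
            iy, ix = int(round(py)), int(round(px))
            sl = (slice(max(iy, 0), iy + width), slice(max(ix, 0), ix + width))
            region = img[sl]
            region[...] = np.where(mask[sl], level, region)

    # small lesions: bright or dark discs
    for _ in range(spec.lesion_count):
        ly, lx = rng.uniform(0.2, 0.8, 2) * n
        r = spec.lesion_radius_px * rng.uniform(0.7, 1.3)
        lesion = _ellipse_mask(n, ly, lx, r, r, 0.0)
        img[lesion & mask] = rng.uniform(0.0, 1.0)

    if spec.bias_field:
        yy, xx = np.mgrid[0:n, 0:n] / n
        gy, gx, gphase = rng.uniform(-1, 1, 3)
        bias = 1.0 + 0.15 * np.sin(np.pi * (gy * yy + gx * xx) + gphase)
        img *= bias

    if spec.noise_sigma > 0:
        img += rng.normal(0.0, spec.noise_sigma, img.shape)

    img = np.clip(img, 0.0, 1.0)
    img[~mask] = 0.0

    x_hr = img.astype(np.float32)
    x_lr = degrade(x_hr, DegradeSpec(factors=spec.factors))
    x_lr[~mask] = 0.0  # masked acquisition: background stays exactly zero
    return PairedSample(x_hr=x_hr, x_lr=x_lr, mask=mask)


def make_dataset(
    n: int,
    spec_template: PhantomSpec | None = None,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    master_seed: int = 0,
) -> dict[str, list[PairedSample]]:
    """Disjoint train/val/test phantom collections with per-item derived seeds."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"split fractions must sum to 1, got {fractions}")
    spec_template = spec_template or PhantomSpec()
    # per-item seeds from one master seed; items are unique, splits disjoint
    seeds = np.random.SeedSequence(master_seed).generate_state(n) % (2**31)
    samples = [make_phantom(replace(spec_template, seed=int(s))) for s in seeds]
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    return {
        "train": samples[:n_train],
        "val": samples[n_train : n_train + n_val],
        "test": samples[n_train + n_val :],
    }
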