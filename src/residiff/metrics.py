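"""Full-reference image-quality metrics: PSNR, SSIM, GMSD, pluggable perceptual.

All three core metrics are computed from their defining formulas on [0, 1]
single-channel slices:

* PSNR = 10 log10(L^2 / MSE) with data range L; a zero-MSE pair is reported
  as the finite dB value at machine-epsilon MSE so aggregates stay finite.
* SSIM follows the original mean-of-local-statistics construction: 11x11
  Gaussian window (sigma 1.5), stabilizers C1 = (K1 L)^2, C2 = (K2 L)^2 with
  K1 = 0.01, K2 = 0.03, Gaussian-weighted (not sample-corrected) covariance.
* GMSD is the standard deviation of the pixel-wise gradient-magnitude
  similarity map (2 m1 m2 + c) / (m1^2 + m2^2 + c) computed with 1/3-scaled
  3x3 Prewitt operators after an optional 2x average-pool, c = 170/255^2 on
  the unit range.

The perceptual slot is a pluggable distance; a multi-scale gradient-magnitude
distance is provided as the no-download option (a feature-network adapter can
be slotted in where pretrained weights are available).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage, signal

__all__ = [
    "MetricConfig",
    "MetricReport",
    "psnr",
    "ssim",
    "gmsd",
    "gradient_magnitude_distance",
    "evaluate_pairs",
    "summarize",
    "PSNR_CAP_DB",
]

# sentinel for identical images: the dB value at MSE = double machine epsilon
PSNR_CAP_DB = 10.0 * math.log10(1.0 / np.finfo(np.float64).eps)


@dataclass(frozen=True)
class MetricConfig:
    data_range: float = 1.0
    ssim_window: int = 11
    ssim_sigma: float = 1.5
    ssim_k1: float = 0.01
    ssim_k2: float = 0.03
    gmsd_c: float = 170.0 / 255.0**2
    gmsd_downsample: bool = True
    perceptual: Callable[[np.ndarray, np.ndarray], float] | None = None

    def __post_init__(self):
        for name in ("data_range", "ssim_sigma", "ssim_k1", "ssim_k2", "gmsd_c"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class MetricReport:
    psnr_db: float
    ssim: float
    gmsd: float
    perceptual: float | None = None

    def as_row(self) -> list[float]:
        row = [self.psnr_db, self.ssim, self.gmsd]
        if self.perceptual is not None:
            row.append(self.perceptual)
        return row


def _check_pair(ref: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.asarray(ref, dtype=np.float64)
    test = np.asarray(test, dtype=np.float64)
    if ref.shape != test.shape:
        raise ValueError(f"shape mismatch: {ref.shape} vs {test.shape}")
    return ref, test


def psnr(ref: np.ndarray, test: np.ndarray, cfg: MetricConfig = MetricConfig()) -> float:
    ref, test = _check_pair(ref, test)
    mse = float(np.mean((ref - test) ** 2))
    if mse == 0.0:
        return 20.0 * math.log10(cfg.data_range) + PSNR_CAP_DB
    return 10.0 * math.log10(cfg.data_range**2 / mse)


def ssim(ref: np.ndarray, test: np.ndarray, cfg: MetricConfig = MetricConfig()) -> float:
    ref, test = _check_pair(ref, test)
    win = cfg.ssim_window
    if min(ref.shape) < win:
        raise ValueError(f"image {ref.shape} smaller than SSIM window {win}")
    pad = (win - 1) // 2
    truncate = pad / cfg.ssim_sigma  # Gaussian kernel truncated to the window

    def f(x):
        return ndimage.gaussian_filter(x, cfg.ssim_sigma, truncate=truncate)

    mu1, mu2 = f(ref), f(test)
    v1 = f(ref * ref) - mu1 * mu1
    v2 = f(test * test) - mu2 * mu2
    cov = f(ref * test) - mu1 * mu2
    c1 = (cfg.ssim_k1 * cfg.data_range) ** 2
    c2 = (cfg.ssim_k2 * cfg.data_range) ** 2
    s = ((2 * mu1 * mu2 + c1) * (2 * cov + c2)) / ((mu1**2 + mu2**2 + c1) * (v1 + v2 + c2))
    return float(s[pad:-pad, pad:-pad].mean())  # interior mean: window fully inside


_PREWITT_X = np.array([[1, 0, -1]] * 3, dtype=np.float64) / 3.0
_PREWITT_Y = _PREWITT_X.T


def _gradient_magnitude(img: np.ndarray) -> np.ndarray:
    gx = signal.convolve2d(img, _PREWITT_X, mode="same", boundary="fill")
    gy = signal.convolve2d(img, _PREWITT_Y, mode="same", boundary="fill")
    return np.sqrt(gx * gx + gy * gy)


def _avg_pool2(img: np.ndarray) -> np.ndarray:
    h, w = (img.shape[0] // 2) * 2, (img.shape[1] // 2) * 2
    img = img[:h, :w]
    return img.reshape(h // 2, 2, w // 2, 2).mean(axis=(1, 3))


def gmsd(ref: np.ndarray, test: np.ndarray, cfg: MetricConfig = MetricConfig()) -> float:
    ref, test = _check_pair(ref, test)
    if cfg.gmsd_downsample:
        ref, test = _avg_pool2(ref), _avg_pool2(test)
    m1 = _gradient_magnitude(ref)
    m2 = _gradient_magnitude(test)
    c = cfg.gmsd_c * (cfg.data_range / 1.0) ** 2
    gms = (2 * m1 * m2 + c) / (m1 * m1 + m2 * m2 + c)
    return float(gms.std())


def gradient_magnitude_distance(
    ref: np.ndarray, test: np.ndarray, n_scales: int = 3
) -> float:
    """Multi-scale gradient-magnitude L1 distance (download-free perceptual slot)."""
    ref, test = _check_pair(ref, test)
    total = 0.0
    for _ in range(n_scales):
        total += float(np.mean(np.abs(_gradient_magnitude(ref) - _gradient_magnitude(test))))
        if min(ref.shape) < 8:
            break
        ref, test = _avg_pool2(ref), _avg_pool2(test)
    return total


def evaluate_pairs(
    pairs: Sequence[tuple[np.ndarray, np.ndarray]],
    cfg: MetricConfig = MetricConfig(),
) -> tuple[list[MetricReport], dict[str, tuple[float, float]]]:
    """Score (restored, reference) pairs; returns per-pair reports and mean +/- sd."""
    if len(pairs) == 0:
        raise ValueError("no pairs to evaluate")
    reports = []
    for restored, reference in pairs:
        reports.append(
            MetricReport(
                psnr_db=psnr(reference, restored, cfg),
                ssim=ssim(reference, restored, cfg),
                gmsd=gmsd(reference, restored, cfg),
                perceptual=(
                    cfg.perceptual(reference, restored) if cfg.perceptual else None
                ),
            )
        )
    return reports, summarize(reports)


def summarize(reports: Sequence[MetricReport]) -> dict[str, tuple[float, float]]:
    """Mean +/- standard deviation per metric, Table-style."""
    out: dict[str, tuple[float, float]] = {}
    for name in ("psnr_db", "ssim", "gmsd", "perceptual"):
        vals = [getattr(r, name) for r in reports]
        if any(v is None for v in vals):
            continue
        arr = np.asarray(vals, dtype=np.float64)
        out[name] = (float(arr.mean()), float(arr.std()))
    return out
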