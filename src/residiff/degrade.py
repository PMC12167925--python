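"""Degradation protocol: per-axis downsampling, then nearest-neighbor
pre-upsampling back to the original grid so HR and LR share a spatial size.

Two ways to state the resolution loss:

* integer (or rational) per-axis ``factors`` — the phantom/test path, e.g.
  the brain preset's 4x4x4;
* ``source_spacing`` -> ``target_spacing`` in mm — the spacing-driven path
  used when the in-plane factor is not an integer (prostate preset:
  0.66 mm -> 2 mm in-plane, 1.5 mm -> 3 mm through-plane).

Downsampling uses linear interpolation with no anti-alias prefilter (the
default behavior of the usual resampling tools); an optional Gaussian
pre-smooth is exposed for study.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["DegradeSpec", "degrade", "nearest_upsample", "bicubic_upsample", "BRAIN_PRESET", "PROSTATE_PRESET"]

_ORDERS = {"nearest": 0, "linear": 1, "cubic": 3}


@dataclass(frozen=True)
class DegradeSpec:
    """Per-axis resolution-loss description.

    Exactly one of ``factors`` or (``source_spacing``, ``target_spacing``)
    must be given; spacings are converted to per-axis factors.
    ``pre_upsample`` is fixed to nearest neighbor.
    """

    factors: tuple[float, ...] | None = None
    source_spacing: tuple[float, ...] | None = None
    target_spacing: tuple[float, ...] | None = None
    interp_down: str = "linear"
    presmooth: bool = False

    def __post_init__(self):
        if (self.factors is None) == (self.target_spacing is None):
            raise ValueError("give either factors or source/target spacing, not both")
        if self.target_spacing is not None and self.source_spacing is None:
            raise ValueError("target_spacing requires source_spacing")
        if self.interp_down not in _ORDERS:
            raise ValueError(f"interp_down must be one of {sorted(_ORDERS)}")
        if any(f < 1 for f in self.resolved_factors()):
            raise ValueError("all downsampling factors must be >= 1")

    def resolved_factors(self) -> tuple[float, ...]:
        if self.factors is not None:
            return tuple(float(f) for f in self.factors)
        return tuple(
            t / s for s, t in zip(self.source_spacing, self.target_spacing)
        )


# brain: 0.8 mm isotropic -> 3.2 mm (4-fold per axis)
BRAIN_PRESET = DegradeSpec(factors=(4, 4, 4))
# prostate: 0.66 x 0.66 x 1.5 mm -> 2 x 2 x 3 mm (~3x in-plane, 2x through-plane)
PROSTATE_PRESET = DegradeSpec(
    source_spacing=(0.66, 0.66, 1.5), target_spacing=(2.0, 2.0, 3.0)
)


def _nearest_indices(n_out: int, n_in: int) -> np.ndarray:
    # nearest-neighbor sample positions mapping an n_in grid onto n_out points
    return np.minimum(((np.arange(n_out) + 0.5) * n_in / n_out).astype(int), n_in - 1)


def nearest_upsample(vol: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Nearest-neighbor resample onto an arbitrary target grid."""
    out = vol
    for axis, n_out in enumerate(shape):
        idx = _nearest_indices(n_out, out.shape[axis])
        out = np.take(out, idx, axis=axis)
    return out


def degrade(vol: np.ndarray, spec: DegradeSpec) -> np.ndarray:
    """Produce the LR counterpart of ``vol`` on the exact original grid."""
    vol = np.asarray(vol, dtype=np.float32)
    factors = spec.resolved_factors()
    if len(factors) != vol.ndim:
        raise ValueError(
            f"{len(factors)} factors for a {vol.ndim}-D volume"
        )
    low_shape = tuple(int(round(n / f)) for n, f in zip(vol.shape, factors))
    if any(n < 1 for n in low_shape):
        raise ValueError(f"factors {factors} exceed volume size {vol.shape}")
    work = vol.astype(np.float64)
    if spec.presmooth:
        sigmas = [f / 2.0 if f > 1 else 0.0 for f in factors]
        work = ndimage.gaussian_filter(work, sigmas)
    zoom = [lo / n for lo, n in zip(low_shape, vol.shape)]
    low = ndimage.zoom(
        work, zoom, order=_ORDERS[spec.interp_down], mode="nearest", grid_mode=True
    )
    return nearest_upsample(low, vol.shape).astype(np.float32)


def bicubic_upsample(vol: np.ndarray, spec: DegradeSpec) -> np.ndarray:
    """Bicubic comparator: recover the raw LR grid, then cubic-resample up.

    The input is the nearest-pre-upsampled LR volume; sampling it back at the
    LR grid positions recovers the raw LR exactly, after which a cubic zoom
    restores the HR grid.  This is the simplest baseline evaluated alongside
    the diffusion sampler.
    """
    vol = np.asarray(vol, dtype=np.float32)
    factors = spec.resolved_factors()
    low_shape = tuple(int(round(n / f)) for n, f in zip(vol.shape, factors))
    low = vol
    for axis, n_out in enumerate(low_shape):
        idx = _nearest_indices(vol.shape[axis], n_out)
        # first occurrence of each LR cell along this axis
        first = np.searchsorted(idx, np.arange(n_out))
        low = np.take(low, first, axis=axis)
    zoom = [n / lo for lo, n in zip(low_shape, vol.shape)]
    up = ndimage.zoom(low.astype(np.float64), zoom, order=3, mode="nearest", grid_mode=True)
    return np.clip(up, 0.0, 1.0).astype(np.float32)
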