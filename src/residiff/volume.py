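"""NIfTI-1 volume I/O and intensity normalization.

Arrays are indexed (row, column, slice), 0-based; voxel spacing is carried
separately in mm.  Slicing for the 2-D model happens along the last axis
after the full 3-D volume has been degraded.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["load_volume", "save_volume", "normalize_volume", "axial_slices"]


def load_volume(path: str | Path) -> tuple[np.ndarray, tuple[float, ...], str]:
    """Read a NIfTI-1 volume; returns (array, voxel spacing in mm, orientation).

    Orientation is recorded as the axis codes of the affine (e.g. 'RAS').
    """
    img = nib.load(str(path))
    affine = img.affine
    if affine is None or not np.isfinite(affine).all():
        raise ValueError(f"{path}: non-finite affine (header field srow/qform)")
    try:
        axcodes = "".join(nib.orientations.aff2axcodes(affine))
    except ValueError as exc:
        raise ValueError(f"{path}: ambiguous orientation in affine: {exc}") from exc
    data = np.asarray(img.get_fdata(), dtype=np.float32)
    spacing = tuple(float(z) for z in img.header.get_zooms()[: data.ndim])
    return data, spacing, axcodes


def save_volume(path: str | Path, vol: np.ndarray, spacing: tuple[float, ...]) -> None:
    affine = np.eye(4)
    for i, s in enumerate(spacing[:3]):
        affine[i, i] = s
    img = nib.Nifti1Image(np.asarray(vol, dtype=np.float32), affine)
    img.header.set_zooms(spacing[: vol.ndim])
    nib.save(img, str(path))


def normalize_volume(
    vol: np.ndarray,
    mask: np.ndarray | None = None,
    clip_percentiles: tuple[float, float] = (0.5, 99.5),
) -> tuple[np.ndarray, tuple[float, float]]:
    """Min-max scale to [0, 1] over masked voxels after percentile clipping.

    Returns the scaled volume (background forced to 0) and the (lo, hi)
    intensity window, which inverts the transform up to clipping loss.
    A constant masked region yields zeros with a warning.
    """
    vol = np.asarray(vol, dtype=np.float32)
    if mask is None:
        mask = np.ones(vol.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask selects no voxels")
    vals = vol[mask]
    lo, hi = np.percentile(vals, clip_percentiles)
    if hi <= lo:
        warnings.warn("constant masked region; returning zeros", stacklevel=2)
        return np.zeros_like(vol), (float(lo), float(lo))
    out = np.clip(vol, lo, hi)
    out = (out - lo) / (hi - lo)
    out[~mask] = 0.0
    return out.astype(np.float32), (float(lo), float(hi))


def axial_slices(vol: np.ndarray) -> list[np.ndarray]:
    """Split a (rows, cols, slices) volume into 2-D slices."""
    return [np.ascontiguousarray(vol[..., k]) for k in range(vol.shape[-1])]
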