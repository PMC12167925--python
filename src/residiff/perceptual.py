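"""Pluggable perceptual distances for the training objective.

The default objective uses no perceptual term.  ``GradMagPerceptual`` is a
differentiable multi-scale gradient-magnitude distance that needs no
pretrained weights; an external feature-network distance (e.g. a pretrained
patch-similarity model) can be slotted into ``LossConfig.perceptual`` with
the same (x0_hat, x_hr) -> scalar Tensor signature where its weights are
available.
"""

from __future__ import annotations

import numpy as np

from .nn import autodiff as ad
from .nn.autodiff import Tensor

__all__ = ["GradMagPerceptual", "null_perceptual"]

_PREWITT_X = (np.array([[1, 0, -1]] * 3) / 3.0).astype(np.float32)


class GradMagPerceptual:
    """Multi-scale smooth-L1 distance between gradient-magnitude maps."""

    def __init__(self, n_scales: int = 2, eps: float = 1e-6):
        self.n_scales = n_scales
        self.eps = eps
        self.kx = Tensor(_PREWITT_X[None, None])
        self.ky = Tensor(_PREWITT_X.T[None, None].copy())

    def _magnitude(self, x: Tensor) -> Tensor:
        xp = ad.reflect_pad2d(x, 1)
        gx = ad.conv2d_valid(xp, self.kx)
        gy = ad.conv2d_valid(xp, self.ky)
        return (gx**2.0 + gy**2.0 + self.eps) ** 0.5

    def __call__(self, a: Tensor, b: Tensor) -> Tensor:
        total = None
        for scale in range(self.n_scales):
            diff = self._magnitude(a) - self._magnitude(b)
            term = ((diff**2.0 + self.eps) ** 0.5).mean()
            total = term if total is None else total + term
            if scale + 1 < self.n_scales:
                a, b = ad.avg_pool2d(a, 2), ad.avg_pool2d(b, 2)
        return total


def null_perceptual(a: Tensor, b: Tensor) -> Tensor:
    """Identically-zero perceptual term (the default objective)."""
    return Tensor(np.zeros((), dtype=a.data.dtype))
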