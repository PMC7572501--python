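"""Unsharp masking, the final stage of the enhancement chain.

Adds a scaled copy of the Gaussian-blur residual back onto the plane.  A
threshold keeps near-flat regions untouched so noise is not amplified.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import LspostError


@dataclass(frozen=True)
class UnsharpParams:
    """Blur scale, sharpening gain, and minimum detail amplitude."""

    sigma: float = 1.5
    amount: float = 0.5
    threshold: int = 0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise LspostError(f"sigma must be positive, got {self.sigma}")
        if self.amount < 0:
            raise LspostError(f"amount must be nonnegative, got {self.amount}")
        if self.threshold < 0:
            raise LspostError(f"threshold must be nonnegative, got {self.threshold}")


def unsharp_mask(plane: np.ndarray, params: UnsharpParams, bit_depth: int) -> np.ndarray:
    """Sharpen one plane by adding ``amount`` times its Gaussian detail.

    ``detail = plane - gaussian(plane, sigma)`` with reflected borders; where
    ``|detail| > threshold`` the output is ``plane + amount * detail``,
    elsewhere the input passes through.  The result is rounded and clipped to
    ``[0, 2**bit_depth - 1]``.  ``amount = 0`` is the exact identity.
    """
    plane = np.asarray(plane)
    if plane.size == 0:
        raise LspostError("plane must be nonempty")
    if params.threshold > (1 << bit_depth) - 1:
        raise LspostError(
            f"threshold {params.threshold} exceeds dtype max {(1 << bit_depth) - 1}"
        )
    x = plane.astype(np.float64)
    detail = x - ndimage.gaussian_filter(x, params.sigma, mode="reflect", truncate=4.0)
    out = np.where(np.abs(detail) > params.threshold, x + params.amount * detail, x)
    return np.clip(np.round(out), 0, (1 << bit_depth) - 1).astype(plane.dtype)
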