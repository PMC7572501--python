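"""Contrast-limited adaptive histogram equalization for high-bit-depth planes.

The plane is divided into a grid of tiles.  Each tile's histogram is clipped
at ``clip_limit * tile_pixels`` and the clipped excess is redistributed
uniformly across all bins in a single pass (bins may thereby exceed the clip
level; no re-clipping).  Each tile's cumulative histogram defines a monotone
intensity mapping onto the full output range, and every pixel's output is the
bilinear blend of the four surrounding tile mappings (tile coordinates are
clamped at the plane border, i.e. border tiles are replicated).

For 16-bit input the bin count defaults to the full 65,536 grey levels so
that very small brightness differences remain separable after equalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import LspostError


@dataclass(frozen=True)
class ClaheParams:
    """Tile grid, clip limit and histogram resolution for adaptive equalization.

    ``n_bins=None`` resolves to ``2**bit_depth`` of the processed plane.
    """

    tile_grid: tuple[int, int] = (8, 8)
    clip_limit: float = 0.01
    n_bins: int | None = None

    def __post_init__(self) -> None:
        rows, cols = self.tile_grid
        if rows < 1 or cols < 1:
            raise LspostError(f"tile_grid must be >= (1, 1), got {self.tile_grid}")
        if not 0 < self.clip_limit <= 1:
            raise LspostError(f"clip_limit must be in (0, 1], got {self.clip_limit}")
        if self.n_bins is not None and self.n_bins < 2:
            raise LspostError(f"n_bins must be >= 2, got {self.n_bins}")


def _clipped_mapping(
    bins: np.ndarray, n_bins: int, clip_limit: float, n_levels: int
) -> np.ndarray:
    """Monotone bin -> output-level mapping from a clip-limited tile histogram."""
    n_pix = bins.size
    hist = np.bincount(bins.ravel(), minlength=n_bins).astype(np.float64)
    clip = clip_limit * n_pix
    excess = np.maximum(hist - clip, 0.0).sum()
    hist = np.minimum(hist, clip) + excess / n_bins
    # mass conservation: redistribution must not change the histogram total
    assert abs(hist.sum() - n_pix) <= 1e-6 * max(n_pix, 1)
    cdf = np.cumsum(hist)
    return np.round(cdf / n_pix * (n_levels - 1))


def _blend_axis(length: int, edges: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-pixel (lower tile, upper tile, upper weight) along one axis.

    Tile centres sit at half-tile offsets; coordinates outside the first/last
    centre clamp to the border tile (replicate).
    """
    centres = (edges[:-1] + edges[1:] - 1) / 2.0
    coords = np.arange(length, dtype=np.float64)
    hi = np.searchsorted(centres, coords)
    lo = np.clip(hi - 1, 0, len(centres) - 1)
    hi = np.clip(hi, 0, len(centres) - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        span = centres[hi] - centres[lo]
        w = np.where(span > 0, (coords - centres[lo]) / np.where(span > 0, span, 1.0), 0.0)
    return lo, hi, np.clip(w, 0.0, 1.0)


def equalize_clahe(plane: np.ndarray, params: ClaheParams, bit_depth: int) -> np.ndarray:
    """Apply contrast-limited adaptive histogram equalization to one plane.

    Parameters
    ----------
    plane
        2D unsigned-integer array with intensities in ``[0, 2**bit_depth - 1]``.
    params
        Tile grid, clip limit, and bin count (``None`` -> ``2**bit_depth``).
    bit_depth
        Bit depth of the plane (8 or 16); fixes the output range.

    Returns
    -------
    numpy.ndarray
        Equalized plane of the same shape and dtype.
    """
    plane = np.asarray(plane)
    if plane.ndim != 2:
        raise LspostError(f"plane must be 2D, got shape {plane.shape}")
    n_levels = 1 << bit_depth
    n_bins = params.n_bins if params.n_bins is not None else n_levels
    if n_bins > n_levels:
        raise LspostError(f"n_bins={n_bins} exceeds dtype capacity {n_levels}")
    rows, cols = params.tile_grid
    h, w = plane.shape
    if rows > h or cols > w:
        raise LspostError(f"tile_grid {params.tile_grid} larger than plane {plane.shape}")

    # bin index of each pixel; integer arithmetic keeps 16-bit exactness
    bins = (plane.astype(np.int64) * n_bins) // n_levels

    row_edges = np.linspace(0, h, rows + 1).round().astype(int)
    col_edges = np.linspace(0, w, cols + 1).round().astype(int)
    mappings = np.empty((rows, cols, n_bins), dtype=np.float64)
    for i in range(rows):
        for j in range(cols):
            tile = bins[row_edges[i] : row_edges[i + 1], col_edges[j] : col_edges[j + 1]]
            mappings[i, j] = _clipped_mapping(tile, n_bins, params.clip_limit, n_levels)

    ri_lo, ri_hi, rw = _blend_axis(h, row_edges)
    ci_lo, ci_hi, cw = _blend_axis(w, col_edges)
    rw2 = rw[:, None]
    cw2 = cw[None, :]
    out = (
        (1 - rw2) * (1 - cw2) * mappings[ri_lo[:, None], ci_lo[None, :], bins]
        + (1 - rw2) * cw2 * mappings[ri_lo[:, None], ci_hi[None, :], bins]
        + rw2 * (1 - cw2) * mappings[ri_hi[:, None], ci_lo[None, :], bins]
        + rw2 * cw2 * mappings[ri_hi[:, None], ci_hi[None, :], bins]
    )
    return np.clip(np.round(out), 0, n_levels - 1).astype(plane.dtype)


def tile_mappings(plane: np.ndarray, params: ClaheParams, bit_depth: int) -> np.ndarray:
    """Return the per-tile bin->level mappings (rows, cols, n_bins); for inspection."""
    plane = np.asarray(plane)
    n_levels = 1 << bit_depth
    n_bins = params.n_bins if params.n_bins is not None else n_levels
    rows, cols = params.tile_grid
    h, w = plane.shape
    bins = (plane.astype(np.int64) * n_bins) // n_levels
    row_edges = np.linspace(0, h, rows + 1).round().astype(int)
    col_edges = np.linspace(0, w, cols + 1).round().astype(int)
    out = np.empty((rows, cols, n_bins), dtype=np.float64)
    for i in range(rows):
        for j in range(cols):
            tile = bins[row_edges[i] : row_edges[i + 1], col_edges[j] : col_edges[j + 1]]
            out[i, j] = _clipped_mapping(tile, n_bins, params.clip_limit, n_levels)
    return out
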