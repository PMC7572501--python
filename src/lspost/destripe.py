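"""Directional stripe suppression via a pie-slice mask in the frequency domain.

Light-sheet recordings of cleared tissue show dark stripe artefacts where
absorbing particles obstruct the illumination sheet.  Stripes drawn at a
spatial angle ``alpha`` from the horizontal image edge (counter-clockwise as
displayed, y down) concentrate their spectral energy along the perpendicular
direction, at ``90 - alpha`` degrees in the centred 2D power spectrum.  A
wedge ("pie slice") of the spectrum around that axis — bounded radially by
``d1``/``d2`` and transversely by widths ``w1``/``w2`` interpolated linearly
in radius — is attenuated, with a Gaussian-smoothed transition to limit
ringing, and the plane is reconstructed by the inverse transform.

Angle conventions: spectral direction of a centred frequency sample
``(u, v)`` (u = row offset, v = column offset) is ``atan2(u, v)`` in degrees
modulo 180; all angles are stored modulo 180 because stripes are undirected.
"""

from __future__ import annotations

import functools
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from .errors import FilterError

logger = logging.getLogger("lspost")


@dataclass(frozen=True)
class PieFilterSpec:
    """Geometry of the pie-slice destriping filter.

    Parameters
    ----------
    alpha_deg
        Spatial stripe angle from the horizontal image edge, degrees in [0, 180).
    d1, d2
        Inner/outer radial bounds in frequency-pixels from the spectrum centre;
        ``d2`` may be the token ``"nyquist"`` (largest representable radius).
    w1, w2
        Full transverse wedge widths at radius ``d1`` and ``d2``.
    edge_sigma
        Standard deviation of the Gaussian transition profile, frequency-pixels.
    attenuation
        Suppression depth in [0, 1]; 1 removes the wedge completely.
    """

    alpha_deg: float
    d1: float = 4.0
    d2: float | str = "nyquist"
    w1: float = 6.0
    w2: float = 40.0
    edge_sigma: float = 2.0
    attenuation: float = 1.0

    def __post_init__(self) -> None:
        if not 0 <= self.alpha_deg < 180:
            raise FilterError(f"alpha_deg must be in [0, 180), got {self.alpha_deg}")
        if self.d1 < 1:
            raise FilterError(f"d1 must be >= 1, got {self.d1}")
        if isinstance(self.d2, str):
            if self.d2 != "nyquist":
                raise FilterError(f"d2 must be a number or 'nyquist', got {self.d2!r}")
        elif self.d2 <= self.d1:
            raise FilterError(f"d2 ({self.d2}) must exceed d1 ({self.d1})")
        if self.w1 <= 0 or self.w2 <= 0:
            raise FilterError("w1 and w2 must be positive")
        if self.edge_sigma < 0:
            raise FilterError(f"edge_sigma must be >= 0, got {self.edge_sigma}")
        if not 0 <= self.attenuation <= 1:
            raise FilterError(f"attenuation must be in [0, 1], got {self.attenuation}")


@dataclass(frozen=True)
class FrequencyMask:
    """Real gain mask over the centred spectrum (zero frequency at array centre)."""

    values: np.ndarray
    shape: tuple[int, int]

    def __post_init__(self) -> None:
        if self.values.shape != self.shape:
            raise FilterError("mask values do not match declared shape")


def _centred_coords(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    m, n = shape
    u = np.arange(m, dtype=np.float64)[:, None] - m // 2
    v = np.arange(n, dtype=np.float64)[None, :] - n // 2
    return u, v


def _max_radius(shape: tuple[int, int]) -> float:
    m, n = shape
    umax = max(m // 2, m - 1 - m // 2)
    vmax = max(n // 2, n - 1 - n // 2)
    return float(np.hypot(umax, vmax))


def _resolve_d2(shape: tuple[int, int], spec: PieFilterSpec) -> float:
    rmax = _max_radius(shape)
    if isinstance(spec.d2, str):
        return rmax
    if spec.d2 > rmax:
        logger.warning("d2=%s exceeds largest radius %.1f; clamped to Nyquist", spec.d2, rmax)
        return rmax
    return float(spec.d2)


def binary_wedge(shape: tuple[int, int], spec: PieFilterSpec) -> np.ndarray:
    """Hard (unsmoothed) wedge region of ``spec`` on the centred spectrum.

    A sample at radius r belongs to the wedge iff ``d1 <= r <= d2`` and its
    perpendicular distance to the wedge axis (spectral angle ``90 - alpha``)
    is at most half the linearly interpolated width ``w1 -> w2``.  The
    condition is even in (u, v), so the point-mirrored wedge is included
    by construction.  DC is excluded (d1 >= 1).
    """
    d2 = _resolve_d2(shape, spec)
    d1 = float(spec.d1)
    if d2 <= d1:
        raise FilterError(f"resolved d2 ({d2}) must exceed d1 ({d1}) for shape {shape}")
    u, v = _centred_coords(shape)
    r = np.hypot(u, v)
    theta = np.deg2rad(90.0 - spec.alpha_deg)
    # axis direction (u, v) = (sin theta, cos theta); normal = (cos theta, -sin theta)
    perp = np.abs(u * np.cos(theta) - v * np.sin(theta))
    with np.errstate(invalid="ignore"):
        half_width = 0.5 * (spec.w1 + (spec.w2 - spec.w1) * (r - d1) / (d2 - d1))
    return (r >= d1) & (r <= d2) & (perp <= half_width)


def _symmetrize(mask: np.ndarray) -> np.ndarray:
    """Average with the point-mirrored mask so even-shape Nyquist lines self-pair."""
    m, n = mask.shape
    rows = (2 * (m // 2) - np.arange(m)) % m
    cols = (2 * (n // 2) - np.arange(n)) % n
    return 0.5 * (mask + mask[np.ix_(rows, cols)])


@functools.lru_cache(maxsize=32)
def _cached_mask(shape: tuple[int, int], spec: PieFilterSpec) -> FrequencyMask:
    wedge = binary_wedge(shape, spec).astype(np.float64)
    if spec.edge_sigma > 0:
        wedge = ndimage.gaussian_filter(wedge, spec.edge_sigma, mode="constant", truncate=4.0)
    wedge = np.clip(wedge, 0.0, 1.0)
    values = 1.0 - spec.attenuation * _symmetrize(wedge)
    values[shape[0] // 2, shape[1] // 2] = 1.0  # DC gain is always unity
    values.setflags(write=False)
    return FrequencyMask(values=values, shape=shape)


def build_pie_mask(shape: tuple[int, int], spec: PieFilterSpec) -> FrequencyMask:
    """Build the smoothed pie-slice gain mask for a plane of ``shape``.

    The returned mask is point-symmetric about the spectrum centre, has all
    gains in [0, 1], and unit gain at the zero-frequency bin.  Masks are
    cached per ``(shape, spec)``.
    """
    if shape[0] < 4 or shape[1] < 4:
        raise FilterError(f"plane shape must be at least 4x4, got {shape}")
    return _cached_mask(tuple(shape), spec)


def filter_plane_real(
    plane: np.ndarray, mask: FrequencyMask, imag_tolerance: float = np.inf
) -> np.ndarray:
    """Frequency-filter a plane and return the raw real result (no rescaling)."""
    plane = np.asarray(plane)
    if plane.shape != mask.shape:
        raise FilterError(f"mask shape {mask.shape} does not match plane shape {plane.shape}")
    spectrum = np.fft.fftshift(np.fft.fft2(plane.astype(np.float64)))
    filtered = np.fft.ifft2(np.fft.ifftshift(spectrum * mask.values))
    residual = float(np.abs(filtered.imag).max())
    if residual >= imag_tolerance:
        raise FilterError(
            f"imaginary residual {residual:.3g} exceeds tolerance; mask not symmetric"
        )
    return filtered.real


def apply_frequency_filter(
    plane: np.ndarray, mask: FrequencyMask, rescale_mode: str = "clip"
) -> np.ndarray:
    """Multiply the plane's centred spectrum by ``mask`` and transform back.

    ``rescale_mode="clip"`` clamps the real-valued result to the input dtype
    range; ``"minmax"`` maps it affinely onto ``[input.min(), input.max()]``.
    The maximum imaginary residual after the inverse transform is asserted to
    be below ``1e-6 * dtype max``; a violation signals a non-symmetric mask.
    """
    plane = np.asarray(plane)
    if rescale_mode not in ("clip", "minmax"):
        raise FilterError(f"rescale_mode must be 'clip' or 'minmax', got {rescale_mode!r}")
    info = np.iinfo(plane.dtype)
    raw = filter_plane_real(plane, mask, imag_tolerance=1e-6 * info.max)
    if rescale_mode == "clip":
        out = np.clip(raw, 0, info.max)
    else:
        lo, hi = float(raw.min()), float(raw.max())
        tlo, thi = float(plane.min()), float(plane.max())
        if hi > lo:
            out = (raw - lo) / (hi - lo) * (thi - tlo) + tlo
        else:
            out = np.full_like(raw, tlo)
    return np.round(out).astype(plane.dtype)


def destripe_plane(
    plane: np.ndarray, spec: PieFilterSpec, rescale_mode: str = "clip"
) -> np.ndarray:
    """Suppress stripes in one plane: build (or reuse) the mask and filter."""
    plane = np.asarray(plane)
    mask = build_pie_mask(plane.shape, spec)
    return apply_frequency_filter(plane, mask, rescale_mode)


def stripe_band_energy(plane: np.ndarray, spec: PieFilterSpec) -> float:
    """Spectral energy (sum of squared magnitudes) inside the hard wedge of ``spec``.

    Uses the unsmoothed wedge region; DC is excluded.  Together with the
    complement and the DC term this partitions the plane's total spectral
    energy (Parseval).
    """
    plane = np.asarray(plane)
    wedge = binary_wedge(plane.shape, spec)
    spectrum = np.fft.fftshift(np.fft.fft2(plane.astype(np.float64)))
    return float((np.abs(spectrum[wedge]) ** 2).sum())


@dataclass(frozen=True)
class AngleEstimate:
    """Stripe-angle estimate with a peak-to-median confidence ratio."""

    angle_deg: float
    peak_ratio: float
    low_confidence: bool

    def __float__(self) -> float:
        return self.angle_deg


def estimate_stripe_angle(
    planes: np.ndarray | Sequence[np.ndarray],
    radial_band: tuple[float, float | str] = (4.0, "nyquist"),
    n_theta: int = 180,
    min_peak_ratio: float = 2.0,
) -> AngleEstimate:
    """Estimate the spatial stripe angle from the dominant spectral direction.

    The median centred log-power spectrum across ``planes`` is accumulated
    over direction bins of width ``180 / n_theta`` degrees (bins centred on
    multiples of the bin width), restricted to ``radial_band`` and excluding
    a 3-pixel guard around the DC crossing.  Bin totals are normalized by
    the number of frequency samples per bin, since diagonal directions reach
    further into the spectrum corners than axis-aligned ones.  The returned
    angle is ``(90 - theta*) mod 180`` for the peak direction ``theta*``;
    the result is flagged low-confidence when the peak bin's mean raw power
    is less than ``min_peak_ratio`` times the median bin's mean raw power.
    """
    if isinstance(planes, np.ndarray) and planes.ndim == 2:
        planes = [planes]
    arrs = [np.asarray(p, dtype=np.float64) for p in planes]
    if not arrs:
        raise FilterError("at least one plane is required")
    shape = arrs[0].shape
    if any(a.shape != shape for a in arrs):
        raise FilterError("all planes must share the same shape")
    if all(float(a.max() - a.min()) == 0.0 for a in arrs):
        raise FilterError("no spectral energy: all planes are constant")

    # Hann window suppresses leakage from the non-periodic image edges, which
    # otherwise shows up as a bright cross along the spectral axes
    wy = np.hanning(shape[0])[:, None]
    wx = np.hanning(shape[1])[None, :]
    window = wy * wx
    spectra = [np.abs(np.fft.fftshift(np.fft.fft2(a * window))) ** 2 for a in arrs]
    log_power = np.median([np.log1p(s) for s in spectra], axis=0)
    raw_power = np.median(spectra, axis=0)
    u, v = _centred_coords(shape)
    r = np.hypot(u, v)
    d1 = float(radial_band[0])
    d2 = _max_radius(shape) if isinstance(radial_band[1], str) else float(radial_band[1])
    if d2 > _max_radius(shape):
        d2 = _max_radius(shape)
    sel = (r >= max(d1, 3.0)) & (r <= d2)  # 3-px guard keeps the DC cross out
    theta = np.degrees(np.arctan2(u, v)) % 180.0
    width = 180.0 / n_theta
    bins = np.round(theta[sel] / width).astype(int) % n_theta
    counts = np.maximum(np.bincount(bins, minlength=n_theta), 1)
    profile = np.bincount(bins, weights=log_power[sel], minlength=n_theta) / counts
    peak = int(np.argmax(profile))
    raw_profile = np.bincount(bins, weights=raw_power[sel], minlength=n_theta) / counts
    med = float(np.median(raw_profile))
    ratio = float(raw_profile[peak] / med) if med > 0 else float("inf")
    alpha = (90.0 - peak * width) % 180.0
    return AngleEstimate(
        angle_deg=alpha, peak_ratio=ratio, low_confidence=ratio < min_peak_ratio
    )
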