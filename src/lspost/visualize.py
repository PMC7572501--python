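"""Intensity-threshold highlighting and brightness-to-colour mapping.

Monochrome autofluorescence recordings distinguish tissue classes only by
brightness: vessels, collagen and erythrocytes are bright, nuclei and fat
dark.  These helpers turn intensity intervals into label volumes and map
brightness onto colour via piecewise-linear control-point tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import LspostError
from .stack_io import ImageStack


@dataclass(frozen=True)
class ThresholdScheme:
    """Ordered, non-overlapping intensity intervals mapped to label names.

    ``intervals`` is a list of ``(label, lower_inclusive, upper_exclusive)``;
    intensities covered by no interval receive ``background_label``.
    """

    intervals: tuple[tuple[str, int, int], ...]
    background_label: str = "background"

    def __post_init__(self) -> None:
        if not self.intervals:
            raise LspostError("threshold scheme must contain at least one interval")
        object.__setattr__(self, "intervals", tuple(tuple(i) for i in self.intervals))
        for label, lo, hi in self.intervals:
            if lo >= hi:
                raise LspostError(f"interval {label!r}: lower bound {lo} must be < upper {hi}")
            if lo < 0:
                raise LspostError(f"interval {label!r}: bounds must be nonnegative")
        ordered = sorted(self.intervals, key=lambda t: t[1])
        for (la, _, hi_a), (lb, lo_b, _) in zip(ordered, ordered[1:]):
            if hi_a > lo_b:
                raise LspostError(f"intervals {la!r} and {lb!r} overlap")

    def validate_for(self, bit_depth: int) -> None:
        top = 1 << bit_depth
        for label, lo, hi in self.intervals:
            if hi > top:
                raise LspostError(
                    f"interval {label!r} upper bound {hi} exceeds 2**{bit_depth} = {top}"
                )


def threshold_segment(
    stack: ImageStack, scheme: ThresholdScheme
) -> tuple[np.ndarray, dict[str, int]]:
    """Assign every voxel exactly one label by intensity interval.

    Returns an integer label volume of the stack's shape and a legend mapping
    label names to label values; the background label is 0.
    """
    scheme.validate_for(stack.bit_depth)
    labels = np.zeros(stack.shape, dtype=np.uint16)
    legend = {scheme.background_label: 0}
    for value, (label, lo, hi) in enumerate(scheme.intervals, start=1):
        legend[label] = value
        labels[(stack.planes >= lo) & (stack.planes < hi)] = value
    return labels, legend


@dataclass(frozen=True)
class ColorMap:
    """Named piecewise-linear colour map over intensity fraction [0, 1].

    Control points are ``(fraction, (r, g, b))`` with fractions strictly
    increasing from exactly 0.0 to exactly 1.0 and channels in [0, 255].
    """

    name: str
    control_points: tuple[tuple[float, tuple[int, int, int]], ...]

    def __post_init__(self) -> None:
        pts = tuple((float(f), tuple(rgb)) for f, rgb in self.control_points)
        object.__setattr__(self, "control_points", pts)
        if len(pts) < 2:
            raise LspostError("colour map needs at least two control points")
        fracs = [f for f, _ in pts]
        if fracs[0] != 0.0 or fracs[-1] != 1.0:
            raise LspostError("control points must start at 0.0 and end at 1.0")
        if any(b <= a for a, b in zip(fracs, fracs[1:])):
            raise LspostError("control-point fractions must be strictly increasing")
        for _, rgb in pts:
            if len(rgb) != 3 or any(not 0 <= c <= 255 for c in rgb):
                raise LspostError(f"RGB values must be triples in [0, 255], got {rgb}")

    def luminances(self) -> list[float]:
        """Rec. 709 luminance of each control point, in control-point order."""
        return [
            0.2126 * r + 0.7152 * g + 0.0722 * b for _, (r, g, b) in self.control_points
        ]


#: Shipped stand-in maps (the recordings' original maps are not published):
#: all three have monotonically increasing control-point luminance.
COLORMAPS: dict[str, ColorMap] = {
    "grayscale": ColorMap("grayscale", ((0.0, (0, 0, 0)), (1.0, (255, 255, 255)))),
    "hotbody": ColorMap(
        "hotbody",
        (
            (0.0, (0, 0, 0)),
            (0.4, (180, 30, 0)),
            (0.75, (255, 200, 0)),
            (1.0, (255, 255, 255)),
        ),
    ),
    "twohue": ColorMap(
        "twohue",
        (
            (0.0, (25, 40, 120)),
            (0.5, (150, 150, 150)),
            (1.0, (255, 200, 90)),
        ),
    ),
}


def _percentile(values: np.ndarray, q: float) -> float:
    return float(np.percentile(values, q))


def apply_colormap(
    stack: ImageStack,
    cmap: ColorMap,
    display_range: tuple[float, float] | str = "auto",
) -> np.ndarray:
    """Map stack intensities to an RGB volume ``(z, y, x, 3)`` of uint8.

    ``display_range`` fixes the intensities mapped to fractions 0 and 1;
    ``"auto"`` uses the stack's 1st and 99th percentiles.
    """
    if display_range == "auto":
        lo = _percentile(stack.planes, 1.0)
        hi = _percentile(stack.planes, 99.0)
        if hi <= lo:  # flat stack: fall back to full dtype range
            lo, hi = 0.0, float(stack.max_value)
    else:
        lo, hi = float(display_range[0]), float(display_range[1])
        if hi <= lo:
            raise LspostError(f"degenerate display range ({lo}, {hi})")
    frac = np.clip((stack.planes.astype(np.float64) - lo) / (hi - lo), 0.0, 1.0)
    xs = np.array([f for f, _ in cmap.control_points])
    rgb = np.empty(stack.shape + (3,), dtype=np.uint8)
    for c in range(3):
        ys = np.array([p[1][c] for p in cmap.control_points], dtype=np.float64)
        rgb[..., c] = np.round(np.interp(frac, xs, ys)).astype(np.uint8)
    return rgb


def extract_virtual_slice(stack: ImageStack, axis: str, index: int) -> np.ndarray:
    """Return the single orthogonal plane at ``index`` along ``axis`` (z, y, or x)."""
    axes = {"z": 0, "y": 1, "x": 2}
    if axis not in axes:
        raise LspostError(f"axis must be one of z, y, x; got {axis!r}")
    ax = axes[axis]
    if not 0 <= index < stack.shape[ax]:
        raise LspostError(
            f"index {index} out of range [0, {stack.shape[ax]}) along axis {axis}"
        )
    return np.take(stack.planes, index, axis=ax)
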