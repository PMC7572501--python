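"""Reading, writing and validation of image stacks and pipeline configuration.

Stacks are ordered sets of 2D grayscale planes indexed ``(z, y, x)`` with
``y`` increasing downward (row-major image convention).  Two on-disk layouts
are supported: a single multi-page TIFF, or a directory of numbered
single-page TIFF slices.  Only unsigned-integer 8/16-bit grayscale data is
accepted; floating-point or colour pages are rejected rather than silently
converted, because the downstream rescaling contracts are defined on integer
dtypes.
"""

from __future__ import annotations

import logging
import re
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import tifffile
import yaml

from .errors import ConfigError, StackIOError

logger = logging.getLogger("lspost")

_ALLOWED_BIT_DEPTHS = (8, 16)
_DTYPE_FOR_DEPTH = {8: np.uint8, 16: np.uint16}

CONFIG_SCHEMA_VERSION = 1

#: Canonical processing order; configs may select a subset, never a permutation.
STAGE_NAMES = ("clahe", "destripe", "unsharp", "segment", "colormap")

#: Per-stage default parameters, filled in for keys omitted from a config.
STAGE_DEFAULTS: dict[str, dict[str, Any]] = {
    "clahe": {"tile_rows": 8, "tile_cols": 8, "clip_limit": 0.01, "n_bins": None},
    "destripe": {
        "alpha": "auto",
        "d1": 4.0,
        "d2": "nyquist",
        "w1": 6.0,
        "w2": 40.0,
        "edge_sigma": 2.0,
        "attenuation": 1.0,
        "rescale_mode": "clip",
    },
    "unsharp": {"sigma": 1.5, "amount": 0.5, "threshold": 0},
    "segment": {"scheme": None, "background_label": "background"},
    "colormap": {"name": "grayscale", "display_range": "auto"},
}

_LOG_LEVELS = ("DEBUG", "INFO", "WARNING", "ERROR")


def configure_logging(level: str = "INFO") -> None:
    """Install a stream handler with timestamped, stage-aware log lines."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
    )
    logger.handlers.clear()
    logger.addHandler(handler)
    logger.setLevel(getattr(logging, level.upper()))


@dataclass
class ImageStack:
    """An ordered set of 2D grayscale planes with bit depth and voxel spacing.

    Parameters
    ----------
    planes
        3D unsigned-integer array of intensities indexed ``(z, y, x)``.
    bit_depth
        8 or 16.  All intensities must lie in ``[0, 2**bit_depth - 1]``.
    voxel_size
        Optional ``(z, y, x)`` voxel spacing in micrometres; strictly positive.
    name
        Free-text identifier used in log lines and reports.
    """

    planes: np.ndarray
    bit_depth: int
    voxel_size: tuple[float, float, float] | None = None
    name: str = ""

    def __post_init__(self) -> None:
        self.planes = np.asarray(self.planes)
        if self.bit_depth not in _ALLOWED_BIT_DEPTHS:
            raise StackIOError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if self.planes.ndim != 3:
            raise StackIOError(
                f"planes must be a 3D (z, y, x) array, got ndim={self.planes.ndim}"
            )
        if self.planes.shape[0] < 1:
            raise StackIOError("stack must contain at least one plane")
        if not np.issubdtype(self.planes.dtype, np.unsignedinteger):
            raise StackIOError(
                f"planes must have an unsigned integer dtype, got {self.planes.dtype}"
            )
        if self.planes.size and int(self.planes.max()) > self.max_value:
            raise StackIOError(
                f"intensities exceed [0, {self.max_value}] for bit_depth {self.bit_depth}"
            )
        if self.voxel_size is not None:
            vs = tuple(float(v) for v in self.voxel_size)
            if len(vs) != 3 or any(v <= 0 for v in vs):
                raise StackIOError(
                    f"voxel_size must be three strictly positive values, got {self.voxel_size}"
                )
            self.voxel_size = vs

    @property
    def n_planes(self) -> int:
        return self.planes.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.planes.shape  # type: ignore[return-value]

    @property
    def max_value(self) -> int:
        """Largest representable intensity, ``2**bit_depth - 1`` (65535 for 16-bit)."""
        return (1 << self.bit_depth) - 1

    @property
    def dtype(self) -> np.dtype:
        return self.planes.dtype

    def with_planes(self, planes: np.ndarray, name: str | None = None) -> "ImageStack":
        """Return a copy of this stack carrying new plane data."""
        return ImageStack(
            planes=planes,
            bit_depth=self.bit_depth,
            voxel_size=self.voxel_size,
            name=self.name if name is None else name,
        )


@dataclass
class StageSpec:
    """A single configured stage: canonical name plus default-filled parameters."""

    name: str
    params: dict[str, Any] = field(default_factory=dict)


@dataclass
class PipelineConfig:
    """Validated, declarative description of a processing run."""

    stages: list[StageSpec]
    input_path: str | None = None
    output_path: str | None = None
    overwrite: bool = False
    log_level: str = "INFO"

    def stage(self, name: str) -> StageSpec | None:
        for s in self.stages:
            if s.name == name:
                return s
        return None

    def effective(self) -> dict[str, Any]:
        """Echo of the default-filled configuration, for reports."""
        return {
            "schema_version": CONFIG_SCHEMA_VERSION,
            "stages": [{"name": s.name, **s.params} for s in self.stages],
            "input": self.input_path,
            "output": self.output_path,
            "overwrite": self.overwrite,
            "log_level": self.log_level,
        }


def _numeric_sort_key(path: Path) -> tuple[int, float, str]:
    """Sort by the value of the last integer group in the stem, then lexicographic.

    Robust to inconsistent zero padding (``s2.tif`` sorts before ``s10.tif``).
    """
    groups = re.findall(r"\d+", path.stem)
    if groups:
        return (0, float(groups[-1]), path.name)
    return (1, 0.0, path.name)


def _validate_page(arr: np.ndarray, origin: str) -> tuple[np.ndarray, int]:
    if arr.ndim != 2:
        raise StackIOError(f"page {origin!r} is not a single grayscale plane (shape {arr.shape})")
    if np.issubdtype(arr.dtype, np.floating):
        raise StackIOError(f"page {origin!r} has floating-point samples; only uint8/uint16 accepted")
    if arr.dtype == np.uint8:
        return arr, 8
    if arr.dtype == np.uint16:
        return arr, 16
    raise StackIOError(
        f"page {origin!r} has unsupported dtype {arr.dtype}; only uint8/uint16 accepted"
    )


def read_stack(path: str | Path, pattern: str | None = None) -> ImageStack:
    """Read an image stack from a multi-page TIFF or a directory of slices.

    Directory slices are ordered by the numeric value of the last integer
    group in their filename (lexicographic fallback), so the result is
    invariant under file-system listing order.

    Raises
    ------
    StackIOError
        If the path is missing, pages mix dimensions or bit depths, or any
        page is colour or floating-point (the message names the page).
    """
    path = Path(path)
    if not path.exists():
        raise StackIOError(f"input path does not exist: {path}")

    if path.is_dir():
        files = sorted(path.glob(pattern or "*.tif*"), key=_numeric_sort_key)
        if not files:
            raise StackIOError(f"no TIFF files matching {pattern or '*.tif*'} in {path}")
        planes: list[np.ndarray] = []
        depth: int | None = None
        shape: tuple[int, int] | None = None
        for f in files:
            arr, d = _validate_page(tifffile.imread(f), f.name)
            if depth is None:
                depth, shape = d, arr.shape
            elif d != depth:
                raise StackIOError(f"mixed bit depths: {f.name} is {d}-bit, expected {depth}-bit")
            elif arr.shape != shape:
                raise StackIOError(
                    f"mixed dimensions: {f.name} is {arr.shape}, expected {shape}"
                )
            planes.append(arr)
        stack = np.stack(planes, axis=0)
        return ImageStack(planes=stack, bit_depth=depth, name=path.name)

    with tifffile.TiffFile(path) as tif:
        pages = [p.asarray() for p in tif.pages]
    if not pages:
        raise StackIOError(f"no pages in TIFF file {path}")
    depth = None
    shape = None
    out = []
    for i, arr in enumerate(pages):
        arr, d = _validate_page(arr, f"{path.name}[page {i}]")
        if depth is None:
            depth, shape = d, arr.shape
        elif d != depth:
            raise StackIOError(
                f"mixed bit depths: page {i} of {path.name} is {d}-bit, expected {depth}-bit"
            )
        elif arr.shape != shape:
            raise StackIOError(
                f"mixed dimensions: page {i} of {path.name} is {arr.shape}, expected {shape}"
            )
        out.append(arr)
    return ImageStack(planes=np.stack(out, axis=0), bit_depth=depth, name=path.stem)


def write_stack(
    stack: ImageStack,
    path: str | Path,
    as_sequence: bool = False,
    overwrite: bool = False,
) -> list[Path]:
    """Write a stack losslessly as a multi-page TIFF or a numbered slice sequence.

    Returns the list of files written.  Refuses to overwrite existing output
    unless ``overwrite`` is set.
    """
    path = Path(path)
    if as_sequence:
        if path.exists() and not path.is_dir():
            raise StackIOError(f"sequence output path exists and is not a directory: {path}")
        path.mkdir(parents=True, exist_ok=True)
        width = max(3, len(str(stack.n_planes - 1)))
        written = []
        for i in range(stack.n_planes):
            f = path / f"slice_{i:0{width}d}.tif"
            if f.exists() and not overwrite:
                raise StackIOError(f"refusing to overwrite existing file {f} (pass overwrite)")
            tifffile.imwrite(f, stack.planes[i], photometric="minisblack")
            written.append(f)
        logger.info("wrote %d slice files to %s", len(written), path)
        return written

    if path.exists() and not overwrite:
        raise StackIOError(f"refusing to overwrite existing file {path} (pass overwrite)")
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, stack.planes, photometric="minisblack")
    logger.info("wrote %d-plane stack to %s", stack.n_planes, path)
    return [path]


def _validate_stage(entry: Mapping[str, Any]) -> StageSpec:
    if not isinstance(entry, Mapping) or "name" not in entry:
        raise ConfigError(f"each stage must be a mapping with a 'name' key, got {entry!r}")
    name = entry["name"]
    if name not in STAGE_NAMES:
        raise ConfigError(
            f"unknown stage {name!r}; valid stages are {', '.join(STAGE_NAMES)}"
        )
    defaults = STAGE_DEFAULTS[name]
    params = dict(defaults)
    for key, value in entry.items():
        if key == "name":
            continue
        if key not in defaults:
            raise ConfigError(f"unknown key {key!r} for stage {name!r}")
        params[key] = value
    return StageSpec(name=name, params=params)


def config_from_mapping(doc: Mapping[str, Any]) -> PipelineConfig:
    """Validate a parsed configuration mapping into a :class:`PipelineConfig`."""
    if not isinstance(doc, Mapping):
        raise ConfigError("config document must be a mapping")
    allowed = {"schema_version", "stages", "input", "output", "overwrite", "log_level"}
    unknown = set(doc) - allowed
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    version = doc.get("schema_version", CONFIG_SCHEMA_VERSION)
    if version != CONFIG_SCHEMA_VERSION:
        raise ConfigError(f"unsupported schema_version {version}; expected {CONFIG_SCHEMA_VERSION}")
    raw_stages = doc.get("stages")
    if not isinstance(raw_stages, Sequence) or isinstance(raw_stages, (str, bytes)) or not raw_stages:
        raise ConfigError("config must list at least one stage under 'stages'")
    stages = [_validate_stage(s) for s in raw_stages]
    seen: set[str] = set()
    for s in stages:
        if s.name in seen:
            raise ConfigError(f"duplicate stage {s.name!r}; each stage may appear at most once")
        seen.add(s.name)
    log_level = str(doc.get("log_level", "INFO")).upper()
    if log_level not in _LOG_LEVELS:
        raise ConfigError(f"log_level must be one of {_LOG_LEVELS}, got {log_level!r}")
    return PipelineConfig(
        stages=stages,
        input_path=doc.get("input"),
        output_path=doc.get("output"),
        overwrite=bool(doc.get("overwrite", False)),
        log_level=log_level,
    )


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML pipeline configuration document."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file does not exist: {path}")
    try:
        doc = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"malformed config document {path}: {exc}") from exc
    if doc is None:
        raise ConfigError(f"empty config document: {path}")
    return config_from_mapping(doc)
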