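"""Stack-level orchestration of the per-plane enhancement chain.

All processing stages operate on 2D planes; a stack run applies the
configured subset of the canonical chain

    clahe -> destripe -> unsharp -> segment -> colormap

independently to every plane.  Stage subsets are allowed; permutations of
the canonical order are rejected rather than silently reordered.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .clahe import ClaheParams, equalize_clahe
from .destripe import (
    PieFilterSpec,
    build_pie_mask,
    apply_frequency_filter,
    estimate_stripe_angle,
    stripe_band_energy,
)
from .errors import PipelineError
from .sharpen import UnsharpParams, unsharp_mask
from .stack_io import ImageStack, PipelineConfig, STAGE_NAMES
from .visualize import COLORMAPS, ColorMap, ThresholdScheme, apply_colormap, threshold_segment

logger = logging.getLogger("lspost")

#: Number of evenly spaced planes used to resolve destripe alpha="auto".
AUTO_ANGLE_MAX_PLANES = 16


@dataclass
class RunReport:
    """Per-run provenance: stage timings, per-plane metrics, config echo, checksums."""

    stage_seconds: dict[str, float] = field(default_factory=dict)
    plane_records: list[dict[str, Any]] = field(default_factory=list)
    params_echo: dict[str, Any] = field(default_factory=dict)
    input_checksum: str = ""
    output_checksum: str = ""
    estimated_alpha_deg: float | None = None

    def to_json(self, **kwargs: Any) -> str:
        return json.dumps(
            {
                "stage_seconds": self.stage_seconds,
                "planes": self.plane_records,
                "effective_config": self.params_echo,
                "input_checksum": self.input_checksum,
                "output_checksum": self.output_checksum,
                "estimated_alpha_deg": self.estimated_alpha_deg,
            },
            **kwargs,
        )


def _checksum(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()


def _check_order(config: PipelineConfig) -> None:
    indices = [STAGE_NAMES.index(s.name) for s in config.stages]
    if indices != sorted(indices):
        raise PipelineError(
            f"stage order {[s.name for s in config.stages]} conflicts with the canonical "
            f"order {list(STAGE_NAMES)}; select a subset, not a permutation"
        )


def _resolve_destripe_spec(stack: ImageStack, params: dict[str, Any]) -> tuple[PieFilterSpec, float | None]:
    alpha = params["alpha"]
    estimated = None
    if isinstance(alpha, str):
        if alpha != "auto":
            raise PipelineError(f"destripe alpha must be a number or 'auto', got {alpha!r}")
        step = max(1, stack.n_planes // AUTO_ANGLE_MAX_PLANES)
        sample = stack.planes[::step][:AUTO_ANGLE_MAX_PLANES]
        est = estimate_stripe_angle(
            list(sample), radial_band=(max(float(params["d1"]), 3.0), params["d2"])
        )
        if est.low_confidence:
            logger.warning(
                "auto angle estimate %.1f deg has low confidence (peak ratio %.2f)",
                est.angle_deg,
                est.peak_ratio,
            )
        alpha = estimated = est.angle_deg
        logger.info("auto-estimated stripe angle: %.2f deg", alpha)
    spec = PieFilterSpec(
        alpha_deg=float(alpha) % 180.0,
        d1=float(params["d1"]),
        d2=params["d2"] if isinstance(params["d2"], str) else float(params["d2"]),
        w1=float(params["w1"]),
        w2=float(params["w2"]),
        edge_sigma=float(params["edge_sigma"]),
        attenuation=float(params["attenuation"]),
    )
    return spec, estimated


def _scheme_from_params(params: dict[str, Any]) -> ThresholdScheme:
    raw = params.get("scheme")
    if not raw:
        raise PipelineError("segment stage requires a 'scheme' list of {label, lo, hi}")
    intervals = tuple((e["label"], int(e["lo"]), int(e["hi"])) for e in raw)
    return ThresholdScheme(intervals=intervals, background_label=params["background_label"])


def process_stack(
    stack: ImageStack, config: PipelineConfig
) -> tuple[ImageStack, RunReport]:
    """Run the configured stages over every plane of ``stack``.

    Returns the processed stack and a :class:`RunReport`.  Label volumes and
    RGB renderings from the ``segment``/``colormap`` stages are attached to
    the report's ``plane_records`` summary and returned via the report's
    ``aux`` attribute set by the CLI layer when writing outputs.
    """
    _check_order(config)
    report = RunReport(params_echo=config.effective(), input_checksum=_checksum(stack.planes))

    stage_names = [s.name for s in config.stages]
    planes = stack.planes.copy()
    bit_depth = stack.bit_depth

    destripe_spec: PieFilterSpec | None = None
    clahe_params: ClaheParams | None = None
    unsharp_params: UnsharpParams | None = None
    rescale_mode = "clip"

    if "clahe" in stage_names:
        p = config.stage("clahe").params
        clahe_params = ClaheParams(
            tile_grid=(int(p["tile_rows"]), int(p["tile_cols"])),
            clip_limit=float(p["clip_limit"]),
            n_bins=None if p["n_bins"] is None else int(p["n_bins"]),
        )
    if "destripe" in stage_names:
        p = config.stage("destripe").params
        destripe_spec, estimated = _resolve_destripe_spec(stack, p)
        report.estimated_alpha_deg = estimated
        rescale_mode = p["rescale_mode"]
        mask = build_pie_mask(planes.shape[1:], destripe_spec)  # built once, cached
    if "unsharp" in stage_names:
        p = config.stage("unsharp").params
        unsharp_params = UnsharpParams(
            sigma=float(p["sigma"]), amount=float(p["amount"]), threshold=int(p["threshold"])
        )

    timings: dict[str, float] = {}
    for k in range(planes.shape[0]):
        record: dict[str, Any] = {"plane": k}
        plane = planes[k]
        if clahe_params is not None:
            t0 = time.perf_counter()
            plane = equalize_clahe(plane, clahe_params, bit_depth)
            timings["clahe"] = timings.get("clahe", 0.0) + time.perf_counter() - t0
        if destripe_spec is not None:
            t0 = time.perf_counter()
            record["stripe_energy_before"] = stripe_band_energy(plane, destripe_spec)
            plane = apply_frequency_filter(plane, mask, rescale_mode)
            record["stripe_energy_after"] = stripe_band_energy(plane, destripe_spec)
            timings["destripe"] = timings.get("destripe", 0.0) + time.perf_counter() - t0
        if unsharp_params is not None:
            t0 = time.perf_counter()
            plane = unsharp_mask(plane, unsharp_params, bit_depth)
            timings["unsharp"] = timings.get("unsharp", 0.0) + time.perf_counter() - t0
        planes[k] = plane
        report.plane_records.append(record)
        logger.debug("processed plane %d/%d", k + 1, planes.shape[0])

    out = stack.with_planes(planes, name=stack.name)
    report.stage_seconds = timings
    report.output_checksum = _checksum(planes)
    return out, report


def run_aux_stages(
    stack: ImageStack, config: PipelineConfig
) -> dict[str, Any]:
    """Execute the segment/colormap stages on a processed stack.

    Returns a dict possibly containing ``labels`` (+ ``legend``) and ``rgb``.
    """
    aux: dict[str, Any] = {}
    seg = config.stage("segment")
    if seg is not None:
        scheme = _scheme_from_params(seg.params)
        labels, legend = threshold_segment(stack, scheme)
        aux["labels"] = labels
        aux["legend"] = legend
    cm = config.stage("colormap")
    if cm is not None:
        name = cm.params["name"]
        if isinstance(name, str):
            if name not in COLORMAPS:
                raise PipelineError(
                    f"unknown colour map {name!r}; shipped maps: {sorted(COLORMAPS)}"
                )
            cmap: ColorMap = COLORMAPS[name]
        else:
            cmap = name
        rng = cm.params["display_range"]
        display = "auto" if rng == "auto" else (float(rng[0]), float(rng[1]))
        aux["rgb"] = apply_colormap(stack, cmap, display)
    return aux
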