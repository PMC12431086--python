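"""Pixel-ratio floral area estimation and end-to-end pipeline orchestration.

The estimator is 2-D photogrammetry at its simplest: with a planar reference
object of known area R_Area in the scene,

    floral_area = F_pixels / R_pixels * R_Area

where F_pixels and R_pixels are the segmented flower and reference pixel
counts.  The published constant for the 7.6 cm brown cardboard square is
R_Area = 58 cm^2 (the geometric 7.6^2 = 57.76 cm^2 is deliberately not
substituted; the constant is configurable).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .errors import ParameterError, ReferenceNotDetectedError
from .imaging import (
    FLOWER,
    REFERENCE,
    InstanceDetection,
    RasterImage,
    extract_tile,
    lift_mask,
    make_tiles,
)
from .segmentation import (
    DEFAULT_CONFIDENCE_THRESHOLD,
    SegmentationResult,
    class_pixel_count,
    class_union_mask,
    filter_by_confidence,
    segment_with_backend,
)

logger = logging.getLogger(__name__)

DEFAULT_REFERENCE_AREA_CM2 = 58.0
DEFAULT_REFERENCE_SIDE_CM = 7.6


@dataclass
class ReferenceSpec:
    """Physical description of the in-scene reference object."""

    area_cm2: float = DEFAULT_REFERENCE_AREA_CM2
    side_cm: Optional[float] = DEFAULT_REFERENCE_SIDE_CM
    description: str = "brown cardboard square"

    def __post_init__(self) -> None:
        if self.area_cm2 <= 0:
            raise ParameterError("reference area must be positive")


@dataclass
class PixelCounts:
    """The F_pixels / R_pixels pair feeding the area ratio."""

    f_pixels: int
    r_pixels: int

    def __post_init__(self) -> None:
        if self.f_pixels < 0 or self.r_pixels < 0:
            raise ParameterError("pixel counts must be non-negative")


@dataclass
class AreaEstimate:
    """The estimated floral area with full provenance."""

    floral_area_cm2: float
    counts: PixelCounts
    reference: ReferenceSpec
    overlay: Optional[np.ndarray] = None
    warnings: list[str] = field(default_factory=list)
    audit: dict = field(default_factory=dict)

    def to_record(self) -> dict:
        rec = {
            "floral_area_cm2": self.floral_area_cm2,
            "f_pixels": self.counts.f_pixels,
            "r_pixels": self.counts.r_pixels,
            "r_area_cm2": self.reference.area_cm2,
            "warnings": list(self.warnings),
        }
        rec.update(self.audit)
        return rec


def estimate_area(counts: PixelCounts, reference: Optional[ReferenceSpec] = None) -> AreaEstimate:
    """Apply the pixel-ratio formula.

    Scale-invariant in the counts: (k*f, k*r) gives the same area.  With no
    reference pixels the image has no scale, so estimation refuses rather
    than guesses.
    """
    reference = reference if reference is not None else ReferenceSpec()
    if counts.r_pixels == 0:
        raise ReferenceNotDetectedError(
            "no reference-object pixels detected; cannot establish the cm/px scale"
        )
    area = counts.f_pixels / counts.r_pixels * reference.area_cm2
    return AreaEstimate(floral_area_cm2=area, counts=counts, reference=reference)


@dataclass
class PipelineConfig:
    """Everything :func:`run_pipeline` needs.

    Defaults follow the deployed-tool constants: a 2x2 tile grid, confidence
    threshold 0.5, reference area 58 cm^2.
    """

    flower_backend: Callable = None
    reference_backend: Callable = None
    tiles: tuple[int, int] = (2, 2)
    confidence_threshold: float = DEFAULT_CONFIDENCE_THRESHOLD
    reference: ReferenceSpec = field(default_factory=ReferenceSpec)
    make_overlay: bool = False


def make_overlay(
    image: RasterImage, flower_mask: np.ndarray, reference_mask: np.ndarray, alpha: float = 0.5
) -> np.ndarray:
    """Two-color visualization: flower mask in red, reference mask in blue."""
    out = image.pixels.astype(np.float64)
    for mask, color in ((flower_mask, (255.0, 40.0, 40.0)), (reference_mask, (40.0, 40.0, 255.0))):
        if mask.any():
            out[mask] = (1 - alpha) * out[mask] + alpha * np.array(color)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def run_pipeline(image: RasterImage, config: PipelineConfig) -> AreaEstimate:
    """Full tiled pipeline: tile, segment with both backends, lift and merge
    masks, filter by confidence, count class pixels globally, estimate area.

    Pixel counts are totalled across all tiles before the ratio is taken.
    Intermediate counts are recorded in ``AreaEstimate.audit``.
    """
    if config.flower_backend is None or config.reference_backend is None:
        raise ParameterError("pipeline config must name both a flower and a reference backend")
    if image.height < 2 or image.width < 2:
        raise ParameterError("image too small to process (need at least 2 px per side)")

    layout = make_tiles(image, *config.tiles)
    detections: list[InstanceDetection] = []
    backend_ids = []
    for backend in (config.flower_backend, config.reference_backend):
        backend_ids.append(getattr(backend, "backend_id", type(backend).__name__))
    for tile_index, rect in enumerate(layout.rects):
        tile = extract_tile(image, rect)
        for backend in (config.flower_backend, config.reference_backend):
            result = segment_with_backend(tile, backend)
            for det in result.detections:
                detections.append(
                    InstanceDetection(
                        label=det.label,
                        mask=lift_mask(det.mask, rect, image.shape),
                        confidence=det.confidence,
                        tile_index=tile_index,
                    )
                )

    merged = SegmentationResult(
        detections, backend_id="+".join(backend_ids), image_ref=image.metadata.get("source_path")
    )
    n_prefilter = len(merged.detections)
    kept = filter_by_confidence(merged, config.confidence_threshold)

    warnings: list[str] = []
    n_reference = sum(1 for d in kept.detections if d.label == REFERENCE)
    if n_reference > 1:
        msg = f"{n_reference} reference components found; expected one — unioning all"
        warnings.append(msg)
        logger.warning(msg)

    f_pixels = class_pixel_count(kept, FLOWER)
    r_pixels = class_pixel_count(kept, REFERENCE)
    estimate = estimate_area(PixelCounts(f_pixels, r_pixels), config.reference)
    estimate.warnings.extend(warnings)
    estimate.audit = {
        "tiles": f"{layout.rows}x{layout.cols}",
        "confidence_threshold": config.confidence_threshold,
        "backend_ids": backend_ids,
        "n_detections_prefilter": n_prefilter,
        "n_detections": len(kept.detections),
    }
    if config.make_overlay:
        flower_mask = class_union_mask(kept, FLOWER, shape=image.shape)
        reference_mask = class_union_mask(kept, REFERENCE, shape=image.shape)
        estimate.overlay = make_overlay(image, flower_mask, reference_mask)
    return estimate
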