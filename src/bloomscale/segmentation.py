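"""The object-segmentation module: backend contract, deterministic classical
HSV backend, confidence filtering, and class pixel counting.

The pipeline keeps two class-specific segmenters (one for flowers, one for
the reference object) behind a single contract so a neural instance
segmenter can be swapped in without touching the rest of the pipeline.

Backend contract
----------------
A backend is a callable ``backend(image: RasterImage) -> iterable of
detections`` where each detection is either an :class:`InstanceDetection` or
a ``(label, mask, confidence)`` tuple with a full-image boolean mask.  A
``backend_id`` attribute is used for provenance; exceptions raised by the
backend (or contract violations such as wrong mask shapes) surface as
:class:`BackendError`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Optional, Sequence, Union

import numpy as np
from skimage import measure, morphology
from skimage.color import rgb2hsv

from .errors import BackendError, MaskShapeError, ParameterError
from .imaging import FLOWER, REFERENCE, InstanceDetection, RasterImage, union_masks

logger = logging.getLogger(__name__)

DEFAULT_CONFIDENCE_THRESHOLD = 0.5


@dataclass
class ColorRange:
    """An HSV box classifier for one color band.

    ``lo``/``hi`` are (hue, saturation, value) on [0, 1]; hue may wrap
    through 0 when ``lo[0] > hi[0]``.  Components smaller than
    ``min_component_px`` are dropped; ``morphology='open_close'`` applies a
    binary opening then closing with a ``kernel_px`` square footprint.
    """

    lo: tuple[float, float, float]
    hi: tuple[float, float, float]
    min_component_px: int = 1
    morphology: str = "none"  # 'none' | 'open_close'
    kernel_px: int = 3

    def __post_init__(self) -> None:
        if self.min_component_px < 1:
            raise ParameterError("min_component_px must be >= 1")
        if self.morphology not in ("none", "open_close"):
            raise ParameterError(f"unknown morphology {self.morphology!r}")
        for i in (1, 2):  # saturation and value may not wrap
            if self.lo[i] > self.hi[i]:
                raise ParameterError("lo must be <= hi channel-wise (except hue)")

    def in_range(self, hsv: np.ndarray) -> np.ndarray:
        """Boolean mask of pixels inside the band (hsv: HxWx3 floats)."""
        h, s, v = hsv[..., 0], hsv[..., 1], hsv[..., 2]
        if self.lo[0] <= self.hi[0]:
            hue_ok = (h >= self.lo[0]) & (h <= self.hi[0])
        else:  # wrap through 0
            hue_ok = (h >= self.lo[0]) | (h <= self.hi[0])
        return (
            hue_ok
            & (s >= self.lo[1])
            & (s <= self.hi[1])
            & (v >= self.lo[2])
            & (v <= self.hi[2])
        )

    def to_dict(self) -> dict:
        return {
            "lo": list(self.lo),
            "hi": list(self.hi),
            "min_component_px": self.min_component_px,
            "morphology": self.morphology,
            "kernel_px": self.kernel_px,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ColorRange":
        return cls(
            lo=tuple(d["lo"]),
            hi=tuple(d["hi"]),
            min_component_px=int(d.get("min_component_px", 1)),
            morphology=str(d.get("morphology", "none")),
            kernel_px=int(d.get("kernel_px", 3)),
        )


@dataclass
class SegmentationResult:
    """Detections from one backend on one image."""

    detections: list[InstanceDetection]
    backend_id: str
    image_ref: Optional[str] = None


def segment_classical(
    image: RasterImage,
    label: str,
    color_range: Union[ColorRange, Sequence[ColorRange]],
) -> SegmentationResult:
    """Deterministic color segmentation: HSV thresholding, optional
    morphology, 8-connected components.

    Each connected component of at least ``min_component_px`` pixels becomes
    one detection with confidence 1.0 (the classical backend has no
    calibrated score).  Identical input yields bit-identical masks.
    """
    ranges = [color_range] if isinstance(color_range, ColorRange) else list(color_range)
    hsv = rgb2hsv(image.pixels)
    detections: list[InstanceDetection] = []
    for cr in ranges:
        mask = cr.in_range(hsv)
        if cr.morphology == "open_close" and mask.any():
            footprint = np.ones((cr.kernel_px, cr.kernel_px), dtype=bool)
            mask = morphology.opening(mask, footprint)
            mask = morphology.closing(mask, footprint)
        if not mask.any():
            continue
        labeled, n = measure.label(mask, connectivity=2, return_num=True)
        sizes = np.bincount(labeled.ravel())
        for comp in range(1, n + 1):
            if sizes[comp] >= cr.min_component_px:
                detections.append(
                    InstanceDetection(label=label, mask=labeled == comp, confidence=1.0)
                )
    return SegmentationResult(detections, backend_id="classical", image_ref=image.metadata.get("source_path"))


class ClassicalBackend:
    """Backend-contract wrapper around :func:`segment_classical`.

    ``ranges`` maps class label -> list of :class:`ColorRange`; one backend
    instance may segment a single class (the pipeline's usual configuration)
    or several.
    """

    def __init__(self, ranges: Mapping[str, Sequence[ColorRange]], backend_id: str = "classical"):
        self.ranges = {k: list(v) for k, v in ranges.items()}
        self.backend_id = backend_id

    def __call__(self, image: RasterImage) -> list[InstanceDetection]:
        out: list[InstanceDetection] = []
        for label, crs in self.ranges.items():
            out.extend(segment_classical(image, label, crs).detections)
        return out


class StubBackend:
    """Fixed-output backend for tests and contract demonstrations."""

    def __init__(self, detections: Sequence, backend_id: str = "stub"):
        self._detections = list(detections)
        self.backend_id = backend_id

    def __call__(self, image: RasterImage):
        return list(self._detections)


def segment_with_backend(image: RasterImage, backend: Callable) -> SegmentationResult:
    """Run any contract-conforming backend and normalize its output.

    Raw tuples are converted to :class:`InstanceDetection`; masks must match
    the image shape.  Backend exceptions and contract violations are wrapped
    in :class:`BackendError` carrying the backend id.
    """
    backend_id = getattr(backend, "backend_id", type(backend).__name__)
    try:
        raw = backend(image)
    except Exception as exc:  # noqa: BLE001 — contract boundary
        raise BackendError(backend_id, f"backend raised {type(exc).__name__}: {exc}") from exc
    detections: list[InstanceDetection] = []
    for item in raw:
        try:
            if isinstance(item, InstanceDetection):
                det = item
            else:
                label, mask, confidence = item
                det = InstanceDetection(label=label, mask=mask, confidence=float(confidence))
        except (MaskShapeError, ParameterError, TypeError, ValueError) as exc:
            raise BackendError(backend_id, f"invalid detection: {exc}") from exc
        if det.mask.shape != image.shape:
            raise BackendError(
                backend_id,
                f"mask shape {det.mask.shape} does not match image shape {image.shape}",
            )
        detections.append(det)
    return SegmentationResult(detections, backend_id=backend_id, image_ref=image.metadata.get("source_path"))


def filter_by_confidence(
    result: SegmentationResult, threshold: float = DEFAULT_CONFIDENCE_THRESHOLD
) -> SegmentationResult:
    """Keep detections with confidence >= threshold (default 0.5), in order."""
    if not (0.0 <= threshold <= 1.0):
        raise ParameterError(f"confidence threshold {threshold} outside [0, 1]")
    kept = [d for d in result.detections if d.confidence >= threshold]
    return SegmentationResult(kept, backend_id=result.backend_id, image_ref=result.image_ref)


def class_union_mask(
    result: SegmentationResult, label: str, shape: Optional[tuple[int, int]] = None
) -> np.ndarray:
    """Union of all detection masks of one class."""
    masks = [d.mask for d in result.detections if d.label == label]
    if not masks and shape is None:
        if result.detections:
            shape = result.detections[0].mask.shape
        else:
            raise MaskShapeError("no detections and no target shape to size the union")
    return union_masks(masks, shape=shape)


def class_pixel_count(result: SegmentationResult, label: str) -> int:
    """Pixels covered by the class, overlaps counted once.

    The union (not the sum) of instance masks is counted: flower pixels are a
    per-pixel quantity, and double-counting overlapping instances would
    inflate the area ratio.
    """
    masks = [d.mask for d in result.detections if d.label == label]
    if not masks:
        return 0
    return int(union_masks(masks).sum())
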