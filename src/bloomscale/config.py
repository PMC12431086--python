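"""Pipeline configuration: built-in defaults, YAML loading, provenance echo.

Precedence is CLI flag > config file > built-in defaults (2x2 tiles,
confidence threshold 0.5, reference area 58 cm^2, classical color backend).
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Optional, Union

import yaml

from .area import DEFAULT_REFERENCE_AREA_CM2, PipelineConfig, ReferenceSpec
from .errors import ParameterError
from .imaging import FLOWER, REFERENCE
from .palettes import default_color_ranges
from .segmentation import ClassicalBackend, ColorRange, DEFAULT_CONFIDENCE_THRESHOLD


def build_pipeline_config(
    tiles: tuple[int, int] = (2, 2),
    confidence_threshold: float = DEFAULT_CONFIDENCE_THRESHOLD,
    reference_area_cm2: float = DEFAULT_REFERENCE_AREA_CM2,
    color_ranges: Optional[Mapping[str, list[ColorRange]]] = None,
    make_overlay: bool = False,
) -> PipelineConfig:
    """Assemble a pipeline config with classical class-specific backends."""
    ranges = dict(color_ranges) if color_ranges is not None else default_color_ranges()
    if FLOWER not in ranges or REFERENCE not in ranges:
        raise ParameterError("color_ranges must define both 'flower' and 'reference' classes")
    return PipelineConfig(
        flower_backend=ClassicalBackend({FLOWER: ranges[FLOWER]}, backend_id="classical-flower"),
        reference_backend=ClassicalBackend(
            {REFERENCE: ranges[REFERENCE]}, backend_id="classical-reference"
        ),
        tiles=tuple(tiles),
        confidence_threshold=confidence_threshold,
        reference=ReferenceSpec(area_cm2=reference_area_cm2),
        make_overlay=make_overlay,
    )


def default_pipeline_config(**overrides) -> PipelineConfig:
    return build_pipeline_config(**overrides)


def load_config(path: Union[str, Path], **overrides) -> PipelineConfig:
    """Build a pipeline config from a YAML file.

    Schema::

        tiles: [2, 2]
        confidence_threshold: 0.5
        reference_area_cm2: 58.0
        color_ranges:
          flower:
            - {lo: [0.045, 0.6, 0.62], hi: [0.18, 1.0, 1.0], min_component_px: 1}
          reference:
            - {lo: [0.04, 0.5, 0.30], hi: [0.12, 0.85, 0.58]}

    Keyword overrides (e.g. from CLI flags) take precedence over the file.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs: dict = {}
    if "tiles" in raw:
        kwargs["tiles"] = tuple(int(x) for x in raw["tiles"])
    if "confidence_threshold" in raw:
        kwargs["confidence_threshold"] = float(raw["confidence_threshold"])
    if "reference_area_cm2" in raw:
        kwargs["reference_area_cm2"] = float(raw["reference_area_cm2"])
    if "color_ranges" in raw:
        kwargs["color_ranges"] = {
            label: [ColorRange.from_dict(d) for d in items]
            for label, items in raw["color_ranges"].items()
        }
    kwargs.update(overrides)
    return build_pipeline_config(**kwargs)


def config_provenance(config: PipelineConfig) -> dict:
    """The effective configuration, echoed into result records."""
    return {
        "tiles": f"{config.tiles[0]}x{config.tiles[1]}",
        "confidence_threshold": config.confidence_threshold,
        "r_area_cm2": config.reference.area_cm2,
        "flower_backend": getattr(config.flower_backend, "backend_id", "?"),
        "reference_backend": getattr(config.reference_backend, "backend_id", "?"),
    }
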