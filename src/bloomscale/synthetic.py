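"""Synthetic flowering-plant scenes with exact ground truth.

The generator emulates the study conditions of the evaluation imagery: potted
plants on a plain background with one brown reference square (7.6 cm side),
flowers in five color categories (T1-T5) and three petal-display shapes
(C1 compound rosettes, C2 continuous blobs, C3 clumps of loose petals),
rendered at scales emulating 60 / 80 / 100 cm capture distances.

All objects lie in a single plane at a single scale (px_per_cm), the working
assumption of 2-D pixel-ratio photogrammetry.  Flower geometry is drawn in
centimeter coordinates, so the same scene spec rendered at several scales
depicts the same physical layout.  Masks are rasterized without
anti-aliasing: the rendered pixels ARE the ground-truth masks, which makes
the pixel counts and cm^2 areas integer-exact oracles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from itertools import product
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .area import PipelineConfig, run_pipeline
from .errors import ParameterError, PlacementError
from .imaging import FLOWER, REFERENCE, RasterImage, save_image, save_mask, union_masks
from .palettes import (
    BACKGROUND_GRAY,
    COLOR_CATEGORY_PALETTES,
    FLOWER_COLORS,
    REFERENCE_BROWN,
)

COLOR_CATEGORIES = tuple(sorted(COLOR_CATEGORY_PALETTES))  # T1..T5
PETAL_CATEGORIES = ("C1", "C2", "C3")
DISTANCES_CM = (60, 80, 100)

PETAL_SHAPES = {
    "C1": "compound_rosette",
    "C2": "continuous_blob",
    "C3": "loose_clump",
}

DEFAULT_CANVAS_CM = (36.0, 48.0)
DEFAULT_REFERENCE_SIDE_CM = 7.6
_SCALE_BASE = 600.0  # px_per_cm * distance_cm at the nominal pinhole geometry


def distance_to_scale(distance_cm: float, side_cm: float = DEFAULT_REFERENCE_SIDE_CM) -> float:
    """Map capture distance to a pixel scale (px_per_cm ~ 1/distance).

    The raw pinhole scale 600/distance is snapped so the reference square
    rasterizes to a whole number of pixels per side (76 / 57 / 46 px for
    60 / 80 / 100 cm; snap error < 0.9%), keeping the rendered reference
    area exact at every distance as the planar-scale model assumes.
    """
    raw = _SCALE_BASE / float(distance_cm)
    side_px = max(1, round(raw * side_cm))
    return side_px / side_cm


@dataclass
class ReferencePlacement:
    side_cm: float = DEFAULT_REFERENCE_SIDE_CM
    center_cm: tuple[float, float] = (5.0, 5.0)  # (y, x) from top-left
    color: tuple[int, int, int] = REFERENCE_BROWN


@dataclass
class FlowerPlacement:
    shape: str  # disk | compound_rosette | continuous_blob | loose_clump
    color_name: str  # key into FLOWER_COLORS
    center_cm: tuple[float, float]
    size_cm: float  # nominal flower diameter
    petal_count: int = 6


@dataclass
class SceneSpec:
    """Full description of one renderable scene."""

    canvas_cm: tuple[float, float] = DEFAULT_CANVAS_CM
    px_per_cm: float = 10.0
    reference: ReferencePlacement = field(default_factory=ReferencePlacement)
    flowers: list[FlowerPlacement] = field(default_factory=list)
    background: tuple[int, int, int] = BACKGROUND_GRAY
    seed: int = 0

    @property
    def canvas_px(self) -> tuple[int, int]:
        return (
            int(round(self.canvas_cm[0] * self.px_per_cm)),
            int(round(self.canvas_cm[1] * self.px_per_cm)),
        )


@dataclass
class GroundTruth:
    """Exact per-instance masks and areas for one rendered scene.

    The identity floral_area_cm2_true = f_pixels_true / r_pixels_true *
    reference_area_cm2_rendered holds exactly by construction and is the
    recovery oracle for the whole pipeline.
    """

    instance_masks: list[tuple[str, np.ndarray]]
    f_pixels_true: int
    r_pixels_true: int
    floral_area_cm2_true: float
    reference_area_cm2_rendered: float

    def masks_for(self, label: str) -> list[np.ndarray]:
        return [m for lab, m in self.instance_masks if lab == label]


def _disk_mask(shape: tuple[int, int], cy: float, cx: float, radius: float) -> np.ndarray:
    """Pixel-center rasterization of a disk (coordinates in pixels)."""
    h, w = shape
    r0 = max(0, int(np.floor(cy - radius - 1)))
    r1 = min(h, int(np.ceil(cy + radius + 1)))
    c0 = max(0, int(np.floor(cx - radius - 1)))
    c1 = min(w, int(np.ceil(cx + radius + 1)))
    out = np.zeros(shape, dtype=bool)
    if r1 <= r0 or c1 <= c0:
        return out
    yy = np.arange(r0, r1) + 0.5
    xx = np.arange(c0, c1) + 0.5
    dy2 = (yy - cy)[:, None] ** 2
    dx2 = (xx - cx)[None, :] ** 2
    out[r0:r1, c0:c1] = dy2 + dx2 <= radius**2
    return out


def _flower_elements(flower: FlowerPlacement, rng: np.random.Generator) -> list[tuple[float, float, float]]:
    """Sub-disks of one flower as (dy_cm, dx_cm, radius_cm) offsets."""
    radius = flower.size_cm / 2.0
    if flower.shape == "disk":
        return [(0.0, 0.0, radius)]
    if flower.shape == "compound_rosette":
        phase = rng.uniform(0, 2 * np.pi)
        elements = [(0.0, 0.0, 0.5 * radius)]
        for j in range(flower.petal_count):
            theta = phase + 2 * np.pi * j / flower.petal_count
            elements.append(
                (0.62 * radius * np.sin(theta), 0.62 * radius * np.cos(theta), 0.42 * radius)
            )
        return elements
    if flower.shape == "continuous_blob":
        elements = [(0.0, 0.0, 0.55 * radius)]
        for _ in range(2):
            theta = rng.uniform(0, 2 * np.pi)
            rho = rng.uniform(0.1, 0.3) * radius
            elements.append((rho * np.sin(theta), rho * np.cos(theta), 0.55 * radius))
        return elements
    if flower.shape == "loose_clump":
        n_petals = int(rng.integers(5, 9))
        elements = []
        for _ in range(n_petals):
            theta = rng.uniform(0, 2 * np.pi)
            rho = rng.uniform(0.0, 0.55) * radius
            elements.append((rho * np.sin(theta), rho * np.cos(theta), 0.16 * radius))
        return elements
    raise ParameterError(f"unknown flower shape {flower.shape!r}")


def generate_scene(spec: SceneSpec) -> tuple[RasterImage, GroundTruth]:
    """Render one scene deterministically (same spec + seed -> bit-identical).

    The visual channel carries a mild per-pixel brightness jitter (RGB scale
    factor in [0.93, 1.05], hue/saturation preserving); the mask channel is
    rendered without anti-aliasing so ground truth stays exact.
    """
    geom_ss, tex_ss = np.random.SeedSequence(spec.seed).spawn(2)
    geom_rng = np.random.default_rng(geom_ss)
    tex_rng = np.random.default_rng(tex_ss)

    h, w = spec.canvas_px
    px = spec.px_per_cm
    canvas = np.empty((h, w, 3), dtype=np.float64)
    canvas[:] = np.asarray(spec.background, dtype=np.float64)

    # reference square, axis-aligned at integer pixel bounds
    side_px = int(round(spec.reference.side_cm * px))
    cy, cx = spec.reference.center_cm
    r0 = int(round(cy * px - side_px / 2))
    c0 = int(round(cx * px - side_px / 2))
    if r0 < 0 or c0 < 0 or r0 + side_px > h or c0 + side_px > w:
        raise PlacementError("reference square does not fit inside the canvas")
    ref_mask = np.zeros((h, w), dtype=bool)
    ref_mask[r0 : r0 + side_px, c0 : c0 + side_px] = True
    canvas[ref_mask] = np.asarray(spec.reference.color, dtype=np.float64)

    flower_masks: list[np.ndarray] = []
    for flower in spec.flowers:
        elements = _flower_elements(flower, geom_rng)
        fy, fx = flower.center_cm
        mask = np.zeros((h, w), dtype=bool)
        for dy, dx, radius in elements:
            mask |= _disk_mask((h, w), (fy + dy) * px, (fx + dx) * px, radius * px)
        if not mask.any():
            raise PlacementError(f"flower at {flower.center_cm} rasterized to zero pixels")
        if (mask & ref_mask).any():
            raise PlacementError("flower overlaps the reference square")
        canvas[mask] = np.asarray(FLOWER_COLORS[flower.color_name], dtype=np.float64)
        flower_masks.append(mask)

    factor = tex_rng.uniform(0.93, 1.05, size=(h, w, 1))
    pixels = np.clip(np.rint(canvas * factor), 0, 255).astype(np.uint8)

    f_true = int(union_masks(flower_masks, shape=(h, w)).sum())
    r_true = int(ref_mask.sum())
    truth = GroundTruth(
        instance_masks=[(REFERENCE, ref_mask)] + [(FLOWER, m) for m in flower_masks],
        f_pixels_true=f_true,
        r_pixels_true=r_true,
        floral_area_cm2_true=f_true / px**2,
        reference_area_cm2_rendered=r_true / px**2,
    )
    image = RasterImage(pixels)
    return image, truth


def _rect_clearance(point: tuple[float, float], rect: tuple[float, float, float, float]) -> float:
    """Distance from a point to an axis-aligned rectangle (cm)."""
    y, x = point
    y0, y1, x0, x1 = rect
    dy = max(y0 - y, 0.0, y - y1)
    dx = max(x0 - x, 0.0, x - x1)
    return float(np.hypot(dy, dx))


def random_scene_spec(
    rng: np.random.Generator,
    color_category: str,
    petal_category: str,
    px_per_cm: float,
    canvas_cm: tuple[float, float] = DEFAULT_CANVAS_CM,
    n_flowers: Optional[int] = None,
    reference_side_cm: float = DEFAULT_REFERENCE_SIDE_CM,
    max_tries: int = 200,
) -> SceneSpec:
    """Draw a random scene layout for one category cell.

    Flowers never overlap the reference square or each other (rejection
    sampling with a clearance radius of 0.55 x flower size, which bounds the
    reach of every petal arrangement).
    """
    if color_category not in COLOR_CATEGORY_PALETTES:
        raise ParameterError(f"unknown color category {color_category!r}")
    if petal_category not in PETAL_SHAPES:
        raise ParameterError(f"unknown petal category {petal_category!r}")
    ch, cw = canvas_cm
    half = reference_side_cm / 2.0
    ref_center = (
        half + 1.2 + rng.uniform(0.0, 1.5),
        half + 1.2 + rng.uniform(0.0, 1.5),
    )
    ref_rect = (
        ref_center[0] - half,
        ref_center[0] + half,
        ref_center[1] - half,
        ref_center[1] + half,
    )
    n = int(n_flowers) if n_flowers is not None else int(rng.integers(3, 7))
    palette = COLOR_CATEGORY_PALETTES[color_category]
    shape = PETAL_SHAPES[petal_category]
    placed: list[tuple[float, float, float]] = []  # (y, x, clearance)
    flowers: list[FlowerPlacement] = []
    for _ in range(n):
        size = float(rng.uniform(3.0, 7.0))
        clearance = 0.55 * size
        for attempt in range(max_tries):
            y = float(rng.uniform(clearance + 0.3, ch - clearance - 0.3))
            x = float(rng.uniform(clearance + 0.3, cw - clearance - 0.3))
            if _rect_clearance((y, x), ref_rect) < clearance + 0.5:
                continue
            if any(np.hypot(y - py, x - px_) < clearance + pc + 0.5 for py, px_, pc in placed):
                continue
            break
        else:
            raise PlacementError(f"could not place flower {len(flowers)} after {max_tries} tries")
        placed.append((y, x, clearance))
        flowers.append(
            FlowerPlacement(
                shape=shape,
                color_name=str(rng.choice(palette)),
                center_cm=(y, x),
                size_cm=size,
                petal_count=int(rng.integers(5, 9)),
            )
        )
    return SceneSpec(
        canvas_cm=canvas_cm,
        px_per_cm=px_per_cm,
        reference=ReferencePlacement(side_cm=reference_side_cm, center_cm=ref_center),
        flowers=flowers,
        seed=int(rng.integers(0, 2**31)),
    )


@dataclass
class BenchmarkItem:
    image_id: str
    spec: SceneSpec
    image: RasterImage
    truth: GroundTruth
    color_category: str
    petal_category: str
    distance_cm: int


def generate_benchmark(
    n_scenes: int = 75,
    seed: int = 0,
    colors: Sequence[str] = COLOR_CATEGORIES,
    petals: Sequence[str] = PETAL_CATEGORIES,
    distances: Sequence[int] = DISTANCES_CM,
    canvas_cm: tuple[float, float] = DEFAULT_CANVAS_CM,
) -> list[BenchmarkItem]:
    """A balanced benchmark over the color x petal x distance factorial grid.

    Scenes are assigned to grid cells round-robin, so every cell receives at
    least floor(n / cells) scenes.  Per-scene seeds derive from the master
    seed; two runs with the same seed are identical.
    """
    if n_scenes < 1:
        raise ParameterError("n_scenes must be >= 1")
    cells = list(product(colors, petals, distances))
    states = np.random.SeedSequence(seed).generate_state(n_scenes)
    items: list[BenchmarkItem] = []
    for i in range(n_scenes):
        color, petal, distance = cells[i % len(cells)]
        rng = np.random.default_rng(int(states[i]) & 0x7FFFFFFF)
        spec = random_scene_spec(rng, color, petal, distance_to_scale(distance), canvas_cm)
        image, truth = generate_scene(spec)
        image.metadata.update(
            {
                "capture_distance_cm": int(distance),
                "color_category": color,
                "petal_category": petal,
            }
        )
        items.append(
            BenchmarkItem(
                image_id=f"scene_{i:03d}",
                spec=spec,
                image=image,
                truth=truth,
                color_category=color,
                petal_category=petal,
                distance_cm=int(distance),
            )
        )
    return items


def rescale_spec(spec: SceneSpec, px_per_cm: float) -> SceneSpec:
    """The same physical scene at a different pixel scale (same seed, so the
    flower geometry in cm is identical)."""
    return replace(spec, px_per_cm=px_per_cm)


def benchmark_eval_table(items: Sequence[BenchmarkItem], config: PipelineConfig) -> pd.DataFrame:
    """Run the pipeline over a benchmark and pair predictions with the exact
    ground-truth areas in the evaluation-table schema."""
    rows = []
    for item in items:
        estimate = run_pipeline(item.image, config)
        rows.append(
            {
                "image_id": item.image_id,
                "predicted_cm2": estimate.floral_area_cm2,
                "measured_cm2": item.truth.floral_area_cm2_true,
                "color_category": item.color_category,
                "petal_category": item.petal_category,
                "distance_cm": item.distance_cm,
            }
        )
    return pd.DataFrame(rows)


def save_scene(
    item: BenchmarkItem, outdir: Path, save_masks: bool = True
) -> dict:
    """Persist one benchmark scene: PNG image, per-instance mask PNGs, and a
    ground-truth JSON sidecar.  Returns the manifest row."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    image_path = outdir / f"{item.image_id}.png"
    save_image(item.image, image_path)
    mask_paths = []
    if save_masks:
        mask_dir = outdir / f"{item.image_id}_masks"
        mask_dir.mkdir(exist_ok=True)
        for idx, (label, mask) in enumerate(item.truth.instance_masks):
            mp = mask_dir / f"{idx:02d}_{label}.png"
            save_mask(mask, mp)
            mask_paths.append(str(mp))
    sidecar = {
        "image_id": item.image_id,
        "f_pixels_true": item.truth.f_pixels_true,
        "r_pixels_true": item.truth.r_pixels_true,
        "floral_area_cm2_true": item.truth.floral_area_cm2_true,
        "reference_area_cm2_rendered": item.truth.reference_area_cm2_rendered,
        "px_per_cm": item.spec.px_per_cm,
        "color_category": item.color_category,
        "petal_category": item.petal_category,
        "distance_cm": item.distance_cm,
        "masks": mask_paths,
    }
    with open(outdir / f"{item.image_id}_truth.json", "w") as fh:
        json.dump(sidecar, fh, indent=2)
    return {
        "image_id": item.image_id,
        "image_path": str(image_path),
        "measured_cm2": item.truth.floral_area_cm2_true,
        "color_category": item.color_category,
        "petal_category": item.petal_category,
        "distance_cm": item.distance_cm,
        "px_per_cm": item.spec.px_per_cm,
    }
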