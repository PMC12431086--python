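"""Raster images, binary masks, and the 2x2 tiling plumbing.

A *mask* throughout this package is a plain 2-D boolean :class:`numpy.ndarray`
in full-image row/col coordinates (0-based, row-major).  Rectangles are
half-open ``[r0, r1) x [c0, c1)``, which keeps tiling and mask lifting free of
off-by-one drift.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
from PIL import Image, ImageOps

from .errors import MaskShapeError, ParameterError, TilingError

# Class labels used across the pipeline.
FLOWER = "flower"
REFERENCE = "reference"
OTHER = "other"


@dataclass
class RasterImage:
    """An 8-bit RGB image plus optional capture metadata.

    Metadata keys in use: ``capture_distance_cm``, ``color_category``,
    ``petal_category``, ``source_path``.
    """

    pixels: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ParameterError(f"expected HxWx3 RGB pixels, got shape {px.shape}")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ParameterError("channel values must lie in [0, 255]")
            px = px.astype(np.uint8)
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ParameterError("image must have at least one pixel per side")
        self.pixels = px

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height, self.width)


@dataclass(frozen=True)
class TileRect:
    """Half-open rectangle [r0, r1) x [c0, c1) in full-image coordinates."""

    r0: int
    r1: int
    c0: int
    c1: int

    @property
    def height(self) -> int:
        return self.r1 - self.r0

    @property
    def width(self) -> int:
        return self.c1 - self.c0

    @property
    def area(self) -> int:
        return self.height * self.width


@dataclass
class TileLayout:
    """A rows x cols grid of disjoint rectangles exactly covering an image."""

    rows: int
    cols: int
    rects: list[TileRect]
    image_shape: tuple[int, int]


@dataclass
class InstanceDetection:
    """One segmented object: class label, full-image mask, confidence."""

    label: str
    mask: np.ndarray
    confidence: float
    tile_index: Optional[int] = None

    def __post_init__(self) -> None:
        m = np.asarray(self.mask)
        if m.ndim != 2 or m.dtype != np.bool_:
            m = m.astype(bool)
            if m.ndim != 2:
                raise MaskShapeError("detection mask must be a 2-D boolean array")
        if not m.any():
            raise ParameterError("detection mask must contain at least one pixel")
        if not (0.0 <= self.confidence <= 1.0):
            raise ParameterError(f"confidence {self.confidence} outside [0, 1]")
        self.mask = m

    @property
    def pixel_count(self) -> int:
        return int(self.mask.sum())


def _split_lengths(total: int, parts: int) -> list[int]:
    # ceil-first remainder rule: the first (total % parts) tiles get the extra pixel
    base, rem = divmod(total, parts)
    return [base + 1] * rem + [base] * (parts - rem)


def make_tiles(image: Union[RasterImage, tuple[int, int]], rows: int = 2, cols: int = 2) -> TileLayout:
    """Split an image into a rows x cols grid of disjoint, exactly-covering tiles.

    The default 2x2 grid yields the four tiles used for sliced inference.  When
    a dimension is not divisible, earlier tiles take the extra pixel, so the
    layout is deterministic.
    """
    shape = image.shape if isinstance(image, RasterImage) else (int(image[0]), int(image[1]))
    h, w = shape
    if rows < 1 or cols < 1:
        raise TilingError(f"grid must be at least 1x1, got {rows}x{cols}")
    if rows > h or cols > w:
        raise TilingError(f"cannot split a {h}x{w} image into a {rows}x{cols} grid")
    row_edges = np.concatenate([[0], np.cumsum(_split_lengths(h, rows))])
    col_edges = np.concatenate([[0], np.cumsum(_split_lengths(w, cols))])
    rects = [
        TileRect(int(row_edges[i]), int(row_edges[i + 1]), int(col_edges[j]), int(col_edges[j + 1]))
        for i in range(rows)
        for j in range(cols)
    ]
    return TileLayout(rows=rows, cols=cols, rects=rects, image_shape=(h, w))


def extract_tile(image: RasterImage, rect: TileRect) -> RasterImage:
    """Crop one tile out of the image (metadata is propagated)."""
    if not (0 <= rect.r0 < rect.r1 <= image.height and 0 <= rect.c0 < rect.c1 <= image.width):
        raise TilingError(f"rect {rect} outside image of shape {image.shape}")
    return RasterImage(image.pixels[rect.r0 : rect.r1, rect.c0 : rect.c1], dict(image.metadata))


def pixel_count(mask: np.ndarray) -> int:
    """Number of true bits in a mask."""
    return int(np.count_nonzero(mask))


def lift_mask(tile_mask: np.ndarray, rect: TileRect, full_shape: tuple[int, int]) -> np.ndarray:
    """Place a tile-local mask into full-image coordinates.

    True bits are translated by (rect.r0, rect.c0); the pixel count is
    preserved exactly.
    """
    tile_mask = np.asarray(tile_mask, dtype=bool)
    if tile_mask.shape != (rect.height, rect.width):
        raise MaskShapeError(
            f"tile mask shape {tile_mask.shape} does not match rect {rect.height}x{rect.width}"
        )
    h, w = full_shape
    if not (0 <= rect.r0 and rect.r1 <= h and 0 <= rect.c0 and rect.c1 <= w):
        raise MaskShapeError(f"rect {rect} outside full shape {full_shape}")
    out = np.zeros((h, w), dtype=bool)
    out[rect.r0 : rect.r1, rect.c0 : rect.c1] = tile_mask
    return out


def union_masks(masks: Iterable[np.ndarray], shape: Optional[tuple[int, int]] = None) -> np.ndarray:
    """Bitwise OR of masks sharing one shape.

    An empty list is valid when ``shape`` is given (result is all-false).
    Overlapping pixels are counted once, so ``pixel_count(union) <= sum of
    pixel counts``, with equality iff the masks are pairwise disjoint.
    """
    masks = [np.asarray(m, dtype=bool) for m in masks]
    if not masks:
        if shape is None:
            raise MaskShapeError("empty mask list requires an explicit target shape")
        return np.zeros(shape, dtype=bool)
    first = masks[0].shape
    if shape is not None and first != tuple(shape):
        raise MaskShapeError(f"mask shape {first} does not match target shape {shape}")
    out = np.zeros(first, dtype=bool)
    for m in masks:
        if m.shape != first:
            raise MaskShapeError(f"mixed mask shapes {first} vs {m.shape}")
        np.logical_or(out, m, out=out)
    return out


# ---------------------------------------------------------------------------
# Image / mask persistence
# ---------------------------------------------------------------------------

def load_image(path: Union[str, Path], metadata: Optional[dict] = None) -> RasterImage:
    """Load a PNG/JPEG/TIFF image as RGB, applying EXIF auto-orientation."""
    with Image.open(path) as im:
        im = ImageOps.exif_transpose(im)
        arr = np.asarray(im.convert("RGB"), dtype=np.uint8)
    meta = dict(metadata or {})
    meta.setdefault("source_path", str(path))
    return RasterImage(arr, meta)


def save_image(image: Union[RasterImage, np.ndarray], path: Union[str, Path]) -> None:
    arr = image.pixels if isinstance(image, RasterImage) else np.asarray(image, dtype=np.uint8)
    Image.fromarray(arr, mode="RGB").save(path)


def load_mask(path: Union[str, Path]) -> np.ndarray:
    """Read a single-channel mask PNG (0 = background, nonzero = object)."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"))
    return arr > 0


def save_mask(mask: np.ndarray, path: Union[str, Path]) -> None:
    """Write a mask as an 8-bit PNG (0 = background, 255 = object)."""
    arr = (np.asarray(mask, dtype=bool).astype(np.uint8)) * 255
    Image.fromarray(arr, mode="L").save(path)
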