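"""Flower and reference color palettes shared by the renderer and the
classical segmenter defaults.

Color categories follow the field convention used for robustness testing:
T1 mixed red/orange/yellow flowers on one plant, T2 pinkish-purple, T3 pink,
T4 red, T5 purple.  The reference object is a matte brown cardboard square.
Hue/saturation/value are on the [0, 1] scale of :func:`skimage.color.rgb2hsv`.
"""

from __future__ import annotations

from .imaging import FLOWER, REFERENCE
from .segmentation import ColorRange

# Base render colors (RGB, 8-bit).  Channel maxima stay <= 240 so the
# renderer's brightness jitter (factor <= 1.05) never clips a channel, which
# would distort hue.
FLOWER_COLORS: dict[str, tuple[int, int, int]] = {
    "red": (210, 25, 35),
    "orange": (230, 120, 25),
    "yellow": (235, 210, 40),
    "pink": (240, 110, 165),
    "pinkish_purple": (215, 80, 200),
    "purple": (150, 55, 220),
}

COLOR_CATEGORY_PALETTES: dict[str, tuple[str, ...]] = {
    "T1": ("red", "orange", "yellow"),
    "T2": ("pinkish_purple",),
    "T3": ("pink",),
    "T4": ("red",),
    "T5": ("purple",),
}

REFERENCE_BROWN = (125, 78, 38)  # HSV approx (0.077, 0.70, 0.49)
BACKGROUND_GRAY = (162, 160, 152)  # low saturation: outside every band


def flower_color_ranges() -> list[ColorRange]:
    """HSV bands covering all five flower color categories.

    Brown is a dark desaturated orange, so the warm band is separated from the
    reference brown by value (flowers render bright, V >= 0.62; the cardboard
    sits near V 0.49).  The plain background is excluded by saturation.
    """
    return [
        # orange + yellow
        ColorRange(lo=(0.045, 0.60, 0.62), hi=(0.18, 1.0, 1.0)),
        # red + pink (hue wraps through 0)
        ColorRange(lo=(0.90, 0.40, 0.62), hi=(0.03, 1.0, 1.0)),
        # purple + pinkish-purple
        ColorRange(lo=(0.70, 0.45, 0.62), hi=(0.90, 1.0, 1.0)),
    ]


def reference_color_range() -> ColorRange:
    """HSV band for the brown cardboard reference square."""
    return ColorRange(lo=(0.04, 0.50, 0.30), hi=(0.12, 0.85, 0.58))


def default_color_ranges() -> dict[str, list[ColorRange]]:
    """Per-class default bands for the classical backend."""
    return {FLOWER: flower_color_ranges(), REFERENCE: [reference_color_range()]}
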