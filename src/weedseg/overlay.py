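"""Annotated overlay images: detected objects tinted, exclusion-zone circles
around crops, target markers and the top/bottom target-generation bands.

Colours follow the field-trial labelling key where one exists (green =
identified weed, yellow = caution/multiple, red = no-treat, pink = crop
misidentified, blue = frame bands); detection overlays tint crops blue and
weeds green, with yellow/red rings marking the caution and ignore radii.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from skimage import draw

from .imaging import CameraGeometry, Frame
from .objects import PlantObject, Target, ZoneConfig

__all__ = ["render_overlay", "CATEGORY_COLOURS"]

# evaluation-category colour key (actual object -> identified as)
CATEGORY_COLOURS = {
    ("weed", "weed"): (0, 200, 0),  # green
    ("weed", "crop"): (0, 80, 255),  # blue
    ("weed", "debris"): (255, 140, 0),  # orange
    ("weed", "missed"): (220, 0, 0),  # red
    ("weed", "multiple"): (230, 220, 0),  # yellow
    ("crop", "weed"): (255, 105, 180),  # pink
    ("crop", "crop"): (20, 20, 20),  # black
}

_CROP_TINT = (0, 80, 255)
_WEED_TINT = (0, 200, 0)
_IGNORE_RING = (220, 0, 0)
_CAUTION_RING = (230, 220, 0)
_BAND_COLOUR = (0, 80, 255)
_TARGET_COLOURS = {
    "treat": (255, 255, 255),
    "careful": (230, 220, 0),
    "ignored": (220, 0, 0),
    "out_of_band": (120, 120, 120),
}


def _ring(img: np.ndarray, centre: tuple[float, float], radius_px: float, colour) -> None:
    rr, cc = draw.circle_perimeter(
        int(round(centre[0])), int(round(centre[1])), max(1, int(round(radius_px))),
        shape=img.shape[:2],
    )
    img[rr, cc] = colour


def _cross(img: np.ndarray, centre: tuple[float, float], colour, arm: int = 4) -> None:
    r, c = int(round(centre[0])), int(round(centre[1]))
    h, w = img.shape[:2]
    rr = np.clip(np.arange(r - arm, r + arm + 1), 0, h - 1)
    cc = np.clip(np.arange(c - arm, c + arm + 1), 0, w - 1)
    img[rr, np.clip(c, 0, w - 1)] = colour
    img[np.clip(r, 0, h - 1), cc] = colour


def render_overlay(
    frame: Frame,
    objects: Sequence[PlantObject],
    targets: Sequence[Target],
    mask: np.ndarray,
    zones: ZoneConfig,
    geometry: CameraGeometry,
) -> np.ndarray:
    """Return an (H, W, 3) uint8 annotated copy of the frame."""
    img = frame.as_array().astype(float)
    # lift the (dim) raw frame for visibility, then tint segmented objects
    img = np.clip(img * 2.0, 0, 255)

    for obj in objects:
        mr, mc, xr, xc = obj.bbox_px
        tint = _CROP_TINT if obj.label == "crop" else _WEED_TINT
        sub = mask[mr:xr, mc:xc]
        region = img[mr:xr, mc:xc]
        region[sub] = 0.55 * region[sub] + 0.45 * np.array(tint)
        img[mr:xr, mc:xc] = region

    out = img.astype(np.uint8)
    ppm = geometry.px_per_mm
    for obj in objects:
        if obj.label == "crop":
            _ring(out, obj.centroid_px, zones.ignore_radius_mm * ppm, _IGNORE_RING)
            _ring(out, obj.centroid_px, zones.caution_radius_mm * ppm, _CAUTION_RING)
    for t in targets:
        _cross(out, t.position_px, _TARGET_COLOURS.get(t.flag, (255, 255, 255)))
    if zones.band_margin_px > 0:
        m = zones.band_margin_px
        out[m - 1, :] = _BAND_COLOUR
        out[-m, :] = _BAND_COLOUR
    return out
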