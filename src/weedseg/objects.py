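"""Connected plant objects, size-exclusion crop/weed labelling and
treatment-target generation with exclusion zones.

Transplanted lettuce is reliably larger than emergent (one-to-three-leaf)
weeds, so classification is by blob area alone: objects at or above the size
threshold are crops, the rest weeds.  Each weed becomes one treatment target;
targets too close to a crop are suppressed or flagged so a herbicide
micro-dose cannot damage the crop, and targets in the top/bottom frame bands
(where parallax error is worst and frames overlap) are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from skimage import measure

from .imaging import CameraGeometry

__all__ = [
    "PlantObject",
    "ZoneConfig",
    "Target",
    "extract_objects",
    "classify_by_size",
    "generate_targets",
    "write_detection_db",
    "DETECTION_DB_COLUMNS",
]

DETECTION_DB_COLUMNS = [
    "frame",
    "timestamp",
    "object_id",
    "label",
    "area_px",
    "area_mm2",
    "x_mm",
    "y_mm",
    "height_mm",
    "flag",
]


@dataclass
class PlantObject:
    """A connected component of the vegetation mask."""

    id: int
    area_px: int
    centroid_px: tuple[float, float]  # (row, col)
    bbox_px: tuple[int, int, int, int]  # (min_row, min_col, max_row, max_col) half-open
    touches_edge: bool
    label: str | None = None  # "crop" | "weed" | None (excluded)
    height_mm: float | None = None
    frame_index: int = 0
    timestamp: float = 0.0


@dataclass
class ZoneConfig:
    """Crop exclusion-zone geometry and frame-band margins.

    The inner disc (``ignore_radius_mm``) around each crop is a no-treat zone:
    dosing there risks crop damage.  The annulus out to ``caution_radius_mm``
    is treat-with-care.  ``zone_assignment="literal"`` instead suppresses every
    target within the outer radius.  ``band_margin_px`` rows at the top and
    bottom of the frame are excluded from target generation.
    """

    ignore_radius_mm: float = 20.0
    caution_radius_mm: float = 40.0
    band_margin_px: int = 0
    target_diameter_mm: float = 20.0
    zone_assignment: str = "damage_rationale"  # or "literal"
    zone_reference: str = "centroid"  # or "bbox_edge"

    def __post_init__(self) -> None:
        if not (self.caution_radius_mm > self.ignore_radius_mm > 0):
            raise ValueError("require caution_radius_mm > ignore_radius_mm > 0")
        if self.zone_assignment not in ("damage_rationale", "literal"):
            raise ValueError("zone_assignment must be 'damage_rationale' or 'literal'")
        if self.zone_reference not in ("centroid", "bbox_edge"):
            raise ValueError("zone_reference must be 'centroid' or 'bbox_edge'")


@dataclass
class Target:
    """A weed-treatment point with parallax-corrected ground coordinates."""

    object_id: int
    position_px: tuple[float, float]
    position_ground_mm: tuple[float, float]
    flag: str  # treat | careful | ignored | out_of_band
    frame_index: int = 0


def extract_objects(
    mask: np.ndarray,
    connectivity: int = 8,
    min_object_area: int = 4,
    frame_index: int = 0,
    timestamp: float = 0.0,
) -> list[PlantObject]:
    """Connected components of a binary mask as unlabelled PlantObjects.

    Components smaller than ``min_object_area`` are discarded as speckle.
    ``touches_edge`` marks components with any pixel on the frame border.
    """
    mask = np.asarray(mask, dtype=bool)
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    lab = measure.label(mask, connectivity=1 if connectivity == 4 else 2)
    h, w = mask.shape
    objects: list[PlantObject] = []
    next_id = 0
    for rp in measure.regionprops(lab):
        if rp.area < min_object_area:
            continue
        mr, mc, xr, xc = rp.bbox
        touches = mr == 0 or mc == 0 or xr == h or xc == w
        objects.append(
            PlantObject(
                id=next_id,
                area_px=int(rp.area),
                centroid_px=(float(rp.centroid[0]), float(rp.centroid[1])),
                bbox_px=(mr, mc, xr, xc),
                touches_edge=touches,
                frame_index=frame_index,
                timestamp=timestamp,
            )
        )
        next_id += 1
    return objects


def classify_by_size(
    objects: Iterable[PlantObject],
    size_threshold_px: int,
    edge_rule: str = "classify",
) -> list[PlantObject]:
    """Label objects crop/weed by area: crop iff ``area_px >= size_threshold_px``.

    With ``edge_rule="exclude"``, objects touching the frame border are left
    unlabelled and take no further part in targeting — partially visible crops
    at frame edges otherwise masquerade as weeds and draw fire.
    """
    if size_threshold_px <= 0:
        raise ValueError("size_threshold_px must be > 0")
    if edge_rule not in ("classify", "exclude"):
        raise ValueError("edge_rule must be 'classify' or 'exclude'")
    out = []
    for obj in objects:
        if edge_rule == "exclude" and obj.touches_edge:
            obj.label = None
        else:
            obj.label = "crop" if obj.area_px >= size_threshold_px else "weed"
        out.append(obj)
    return out


def _ground_position(
    obj: PlantObject, geometry: CameraGeometry, height_mm: float | None
) -> tuple[float, float]:
    from .stereo import parallax_correct  # local import to avoid cycle

    if height_mm:
        return parallax_correct(obj.centroid_px, height_mm, geometry)
    return geometry.px_to_ground_mm(*obj.centroid_px)


def generate_targets(
    objects: Sequence[PlantObject],
    zones: ZoneConfig,
    geometry: CameraGeometry,
    heights: dict[int, float] | None = None,
) -> list[Target]:
    """One treatment target per weed, flagged by crop proximity and frame bands.

    Distances are centroid-to-centroid in ground millimetres, parallax-corrected
    when per-object heights are available.  Flag precedence: out_of_band, then
    ignored (inside the no-treat disc of any crop), then careful (caution
    annulus, or the weed touches a frame edge), else treat.
    """
    if geometry is None:
        raise ValueError("camera geometry is required to generate targets")
    heights = heights or {}

    def h_of(obj: PlantObject) -> float | None:
        return heights.get(obj.id, obj.height_mm)

    crops = [o for o in objects if o.label == "crop"]
    crop_pos = np.array(
        [_ground_position(o, geometry, h_of(o)) for o in crops]
    ).reshape(-1, 2)

    targets: list[Target] = []
    for obj in objects:
        if obj.label != "weed":
            continue
        pos_mm = _ground_position(obj, geometry, h_of(obj))
        row = obj.centroid_px[0]
        if zones.band_margin_px > 0 and (
            row < zones.band_margin_px
            or row >= geometry.frame_height_px - zones.band_margin_px
        ):
            flag = "out_of_band"
        else:
            d = (
                float(np.min(np.hypot(*(crop_pos - np.asarray(pos_mm)).T)))
                if len(crop_pos)
                else np.inf
            )
            if zones.zone_assignment == "literal":
                ignore_r = zones.caution_radius_mm
                careful_r = zones.ignore_radius_mm  # subsumed by the ignore disc
            else:
                ignore_r = zones.ignore_radius_mm
                careful_r = zones.caution_radius_mm
            if d <= ignore_r:
                flag = "ignored"
            elif d <= careful_r or obj.touches_edge:
                flag = "careful"
            else:
                flag = "treat"
        targets.append(
            Target(
                object_id=obj.id,
                position_px=obj.centroid_px,
                position_ground_mm=(float(pos_mm[0]), float(pos_mm[1])),
                flag=flag,
                frame_index=obj.frame_index,
            )
        )
    return targets


def write_detection_db(
    objects: Sequence[PlantObject],
    targets: Sequence[Target],
    path: str,
    geometry: CameraGeometry | None = None,
) -> pd.DataFrame:
    """Write one CSV row per detected object (crops included), sorted by
    (frame, object id); returns the DataFrame that was written.

    ``area_mm2 = area_px / px_per_mm^2``; the target flag column is empty for
    crops and excluded objects.
    """
    flag_by_id = {(t.frame_index, t.object_id): t.flag for t in targets}
    pos_by_id = {(t.frame_index, t.object_id): t.position_ground_mm for t in targets}
    rows = []
    for obj in objects:
        key = (obj.frame_index, obj.id)
        if geometry is not None:
            ppm = geometry.px_per_mm
            x_mm, y_mm = pos_by_id.get(
                key, geometry.px_to_ground_mm(*obj.centroid_px)
            )
            area_mm2 = obj.area_px / ppm**2
        else:
            x_mm = y_mm = area_mm2 = np.nan
        rows.append(
            {
                "frame": obj.frame_index,
                "timestamp": obj.timestamp,
                "object_id": obj.id,
                "label": obj.label if obj.label else "",
                "area_px": obj.area_px,
                "area_mm2": area_mm2,
                "x_mm": x_mm,
                "y_mm": y_mm,
                "height_mm": obj.height_mm if obj.height_mm is not None else "",
                "flag": flag_by_id.get(key, ""),
            }
        )
    df = pd.DataFrame(rows, columns=DETECTION_DB_COLUMNS)
    df = df.sort_values(["frame", "object_id"]).reset_index(drop=True)
    df.to_csv(path, index=False)
    return df
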