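"""Glue running the full detection chain on one frame or a stereo pair:
RGNIR index → quantise → multi-Otsu → vegetation mask → connected objects →
size exclusion → (optional kinematic-stereo heights + parallax correction) →
treatment targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import CalibrationProfile
from .imaging import Frame
from .objects import (
    PlantObject,
    Target,
    extract_objects,
    classify_by_size,
    generate_targets,
)
from .segmentation import (
    compute_rgnir,
    multi_otsu,
    quantise_index,
    select_vegetation_classes,
    vegetation_mask,
)
from .stereo import (
    InvalidDisparityError,
    dense_flow,
    enhance_texture,
    object_height,
)

__all__ = ["DetectionResult", "detect_frame", "detect_pair"]


@dataclass
class DetectionResult:
    """Everything one frame's detection produced."""

    frame_index: int
    objects: list[PlantObject]
    targets: list[Target]
    mask: np.ndarray
    quantised: np.ndarray
    thresholds: tuple[int, ...]
    heights: dict[int, float] = field(default_factory=dict)
    positions: dict[int, tuple[float, float]] = field(default_factory=dict)

    def detections_table(self) -> pd.DataFrame:
        """Labelled detections with ground coordinates, for the evaluator."""
        rows = []
        for obj in self.objects:
            if obj.label is None:
                continue
            x_mm, y_mm = self.positions.get(obj.id, (np.nan, np.nan))
            rows.append(
                {
                    "object_id": obj.id,
                    "label": obj.label,
                    "area_px": obj.area_px,
                    "x_mm": x_mm,
                    "y_mm": y_mm,
                    "height_mm": self.heights.get(obj.id, np.nan),
                }
            )
        return pd.DataFrame(
            rows, columns=["object_id", "label", "area_px", "x_mm", "y_mm", "height_mm"]
        )


def _segment(frame: Frame, profile: CalibrationProfile):
    idx = compute_rgnir(frame, profile.background, profile.weights)
    quantised, hist = quantise_index(idx)
    thresholds = multi_otsu(hist, profile.n_thresholds)
    veg = (
        set(profile.vegetation_classes)
        if profile.vegetation_classes is not None
        else select_vegetation_classes(hist, thresholds)
    )
    mask = vegetation_mask(quantised, thresholds, veg)
    return idx, quantised, thresholds, mask


def detect_frame(frame: Frame, profile: CalibrationProfile) -> DetectionResult:
    """Run the single-frame pipeline (no heights; positions uncorrected)."""
    _, quantised, thresholds, mask = _segment(frame, profile)
    objects = extract_objects(
        mask,
        connectivity=profile.connectivity,
        min_object_area=profile.min_object_area,
        frame_index=frame.index,
        timestamp=frame.timestamp,
    )
    objects = classify_by_size(objects, profile.size_threshold_px, profile.edge_rule)
    targets = generate_targets(objects, profile.zones, profile.geometry)
    positions = {
        o.id: profile.geometry.px_to_ground_mm(*o.centroid_px)
        for o in objects
        if o.label is not None
    }
    return DetectionResult(
        frame_index=frame.index,
        objects=objects,
        targets=targets,
        mask=mask,
        quantised=quantised,
        thresholds=thresholds,
        positions=positions,
    )


def detect_pair(
    frame0: Frame, frame1: Frame, profile: CalibrationProfile
) -> DetectionResult:
    """Run the stereo pipeline on two consecutive frames.

    Objects are extracted from the first frame; per-object heights come from
    dense flow between the texture-enhanced RGNIR greyscales, and target
    positions are parallax-corrected with those heights.  Objects whose flow
    is unusable keep no height (treated as ground level).
    """
    idx0, quantised, thresholds, mask = _segment(frame0, profile)
    idx1 = compute_rgnir(frame1, profile.background, profile.weights)

    w = profile.stereo.laplacian_weight
    g0 = enhance_texture(idx0.values, w)
    g1 = enhance_texture(idx1.values, w)
    flow = dense_flow(g0, g1, profile.stereo.flow_params)

    objects = extract_objects(
        mask,
        connectivity=profile.connectivity,
        min_object_area=profile.min_object_area,
        frame_index=frame0.index,
        timestamp=frame0.timestamp,
    )
    objects = classify_by_size(objects, profile.size_threshold_px, profile.edge_rule)

    heights: dict[int, float] = {}
    for obj in objects:
        # sample a window scaled to the object so the median spans most of its
        # interior — a fixed small window is hostage to local flow blips
        radius_px = np.sqrt(obj.area_px / np.pi)
        window = 2 * int(np.clip(0.7 * radius_px, 2, 15)) + 1
        try:
            h = object_height(flow, obj, profile.stereo, profile.geometry, window=window)
        except (InvalidDisparityError, IndexError):
            continue
        heights[obj.id] = h
        obj.height_mm = h

    targets = generate_targets(objects, profile.zones, profile.geometry, heights)
    from .stereo import parallax_correct

    positions = {}
    for o in objects:
        if o.label is None:
            continue
        h = heights.get(o.id, 0.0)
        if h:
            positions[o.id] = parallax_correct(o.centroid_px, h, profile.geometry)
        else:
            positions[o.id] = profile.geometry.px_to_ground_mm(*o.centroid_px)
    return DetectionResult(
        frame_index=frame0.index,
        objects=objects,
        targets=targets,
        mask=mask,
        quantised=quantised,
        thresholds=thresholds,
        heights=heights,
        positions=positions,
    )
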