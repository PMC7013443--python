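"""Match detections against ground truth and compute identification metrics.

Each truth object receives exactly one category.  Weeds: ``weed`` (one
matched weed-labelled detection), ``crop`` (matched to a crop-labelled
detection), ``multiple`` (two or more matched detections — typically one per
leaf), or ``missed``.  Crops: ``crop``, ``weed`` (misidentified) or
``missed``.  Detections matching no crop/weed truth object are false
positives; those overlapping a debris object are debris false positives
(stones and twigs drawing a dose).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MatchResult",
    "MetricsReport",
    "match_detections",
    "match_detections_by_frame",
    "compute_metrics",
]


@dataclass
class MatchResult:
    """Per-truth categories and per-detection dispositions."""

    truth_categories: dict[int, str]  # truth row id -> category
    truth_kinds: dict[int, str]
    detection_matches: dict[int, int | None]  # det id -> truth id or None
    detection_categories: dict[int, str]  # matched | debris_false_positive | false_positive
    match_radius_mm: float


@dataclass
class MetricsReport:
    """Identification metrics; ``None`` marks an undefined (0/0) percentage."""

    weed_identified_pct: float | None
    weed_identified_lenient_pct: float | None
    weed_multiple_pct: float | None
    debris_of_targets_pct: float | None
    crop_misidentified_pct: float | None
    counts: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "weed_identified_pct": self.weed_identified_pct,
            "weed_identified_lenient_pct": self.weed_identified_lenient_pct,
            "weed_multiple_pct": self.weed_multiple_pct,
            "debris_of_targets_pct": self.debris_of_targets_pct,
            "crop_misidentified_pct": self.crop_misidentified_pct,
            "counts": self.counts,
        }


def match_detections(
    detections: pd.DataFrame,
    truth: pd.DataFrame,
    match_radius_mm: float = 20.0,
) -> MatchResult:
    """Greedy nearest-neighbour matching of detections to truth objects.

    ``detections`` needs columns (label, x_mm, y_mm); ``truth`` needs
    (kind, x_mm, y_mm).  Each detection is assigned to its nearest crop/weed
    truth object within the radius (ties by distance, then lowest id); truth
    objects may collect several detections.  The default radius is the
    micro-dose footprint diameter (20 mm): a detection within it still treats
    the weed.
    """
    if match_radius_mm <= 0:
        raise ValueError("match radius must be > 0")
    det_ids = list(detections.index)
    truth_plant = truth[truth["kind"].isin(["crop", "weed"])]
    truth_debris = truth[truth["kind"] == "debris"]

    det_xy = detections[["x_mm", "y_mm"]].to_numpy(dtype=float).reshape(-1, 2)
    tp_xy = truth_plant[["x_mm", "y_mm"]].to_numpy(dtype=float).reshape(-1, 2)

    detection_matches: dict[int, int | None] = {}
    matched_by_truth: dict[int, list[int]] = {int(t): [] for t in truth_plant.index}
    for k, det_id in enumerate(det_ids):
        match = None
        if len(tp_xy):
            dists = np.hypot(*(tp_xy - det_xy[k]).T)
            order = np.lexsort((np.array(truth_plant.index), dists))
            best = order[0]
            if dists[best] <= match_radius_mm:
                match = int(truth_plant.index[best])
        detection_matches[det_id] = match
        if match is not None:
            matched_by_truth[match].append(det_id)

    truth_categories: dict[int, str] = {}
    truth_kinds: dict[int, str] = {}
    for t in truth_plant.index:
        kind = truth_plant.loc[t, "kind"]
        truth_kinds[int(t)] = kind
        dets = matched_by_truth[int(t)]
        if not dets:
            truth_categories[int(t)] = "missed"
        elif kind == "weed" and len(dets) >= 2:
            truth_categories[int(t)] = "multiple"
        else:
            label = detections.loc[dets[0], "label"]
            truth_categories[int(t)] = "weed" if label == "weed" else "crop"

    db_xy = truth_debris[["x_mm", "y_mm"]].to_numpy(dtype=float).reshape(-1, 2)
    detection_categories: dict[int, str] = {}
    for k, det_id in enumerate(det_ids):
        if detection_matches[det_id] is not None:
            detection_categories[det_id] = "matched"
        elif len(db_xy) and np.min(np.hypot(*(db_xy - det_xy[k]).T)) <= match_radius_mm:
            detection_categories[det_id] = "debris_false_positive"
        else:
            detection_categories[det_id] = "false_positive"

    return MatchResult(
        truth_categories=truth_categories,
        truth_kinds=truth_kinds,
        detection_matches=detection_matches,
        detection_categories=detection_categories,
        match_radius_mm=match_radius_mm,
    )


def match_detections_by_frame(
    detections: pd.DataFrame,
    truth: pd.DataFrame,
    match_radius_mm: float = 20.0,
) -> MatchResult:
    """Frame-wise matching merged into one result.

    When both tables carry a ``frame`` column, each annotated frame is matched
    independently (detections from frames without ground truth are dropped —
    you evaluate the frames you annotated); without the column this is plain
    :func:`match_detections`.
    """
    if "frame" not in detections.columns or "frame" not in truth.columns:
        return match_detections(detections, truth, match_radius_mm)
    merged = MatchResult({}, {}, {}, {}, match_radius_mm)
    for f in sorted(truth["frame"].unique()):
        mr = match_detections(
            detections[detections["frame"] == f], truth[truth["frame"] == f],
            match_radius_mm,
        )
        merged.truth_categories.update(mr.truth_categories)
        merged.truth_kinds.update(mr.truth_kinds)
        merged.detection_matches.update(mr.detection_matches)
        merged.detection_categories.update(mr.detection_categories)
    return merged


def _pct(num: int, den: int) -> float | None:
    return None if den == 0 else 100.0 * num / den


def compute_metrics(match: MatchResult) -> MetricsReport:
    """Percentages over truth weeds, truth crops and emitted detections.

    The strict weed identification rate counts only singly-matched weeds;
    the lenient rate also counts multiple-target weeds, which a dosing
    actuator can still treat.
    """
    weeds = [t for t, k in match.truth_kinds.items() if k == "weed"]
    crops = [t for t, k in match.truth_kinds.items() if k == "crop"]
    cat = match.truth_categories
    n_weed_ok = sum(cat[t] == "weed" for t in weeds)
    n_weed_multi = sum(cat[t] == "multiple" for t in weeds)
    n_crop_as_weed = sum(cat[t] == "weed" for t in crops)
    n_det = len(match.detection_categories)
    n_debris_fp = sum(
        c == "debris_false_positive" for c in match.detection_categories.values()
    )
    counts = {
        "truth_weeds": len(weeds),
        "truth_crops": len(crops),
        "weeds_identified": n_weed_ok,
        "weeds_multiple": n_weed_multi,
        "weeds_missed": sum(cat[t] == "missed" for t in weeds),
        "weeds_as_crop": sum(cat[t] == "crop" for t in weeds),
        "crops_misidentified": n_crop_as_weed,
        "detections": n_det,
        "debris_false_positives": n_debris_fp,
        "false_positives": sum(
            c == "false_positive" for c in match.detection_categories.values()
        ),
    }
    return MetricsReport(
        weed_identified_pct=_pct(n_weed_ok, len(weeds)),
        weed_identified_lenient_pct=_pct(n_weed_ok + n_weed_multi, len(weeds)),
        weed_multiple_pct=_pct(n_weed_multi, len(weeds)),
        debris_of_targets_pct=_pct(n_debris_fp, n_det),
        crop_misidentified_pct=_pct(n_crop_as_weed, len(crops)),
        counts=counts,
    )
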