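"""Calibration profiles: every tunable of the detection pipeline in one
YAML-serialisable object, plus background capture and an offline grid-search
tuner.

The field workflow captures a dark background frame (illumination off, black
box) and a couple of reference frames, then tunes the index weights and size
threshold until the processed output looks right.  Here that manual loop is
an exhaustive grid search scored against labelled frames: the objective is
the unweighted mean of weed recall and crop recall under the evaluation
matcher, so improving weed pickup cannot silently sacrifice crops.
"""

from __future__ import annotations

import datetime
import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .imaging import CameraGeometry, ChannelMixMatrix, Frame, IlluminationConfig
from .objects import ZoneConfig
from .segmentation import BackgroundCorrection, IndexWeights
from .stereo import StereoConfig

__all__ = [
    "CalibrationProfile",
    "ProfileValidationError",
    "capture_background",
    "tune_profile",
    "save_profile",
    "load_profile",
]

SCHEMA_VERSION = 1


class ProfileValidationError(ValueError):
    pass


@dataclass
class CalibrationProfile:
    """All pipeline tunables; round-trips bit-exactly through YAML."""

    weights: IndexWeights = field(default_factory=IndexWeights)
    background: BackgroundCorrection = field(default_factory=BackgroundCorrection)
    n_thresholds: int = 2
    vegetation_classes: tuple[int, ...] | None = None  # None = top class
    min_object_area: int = 4
    connectivity: int = 8
    size_threshold_px: int = 400
    edge_rule: str = "classify"
    zones: ZoneConfig = field(default_factory=ZoneConfig)
    geometry: CameraGeometry = field(default_factory=CameraGeometry)
    stereo: StereoConfig = field(default_factory=StereoConfig)
    mix: ChannelMixMatrix = field(default_factory=ChannelMixMatrix)
    illum: IlluminationConfig = field(default_factory=IlluminationConfig)
    name: str = "default"
    created: str = ""

    def __post_init__(self) -> None:
        if not self.created:
            self.created = datetime.datetime.now(datetime.timezone.utc).isoformat()
        if not (1 <= self.n_thresholds <= 4):
            raise ProfileValidationError("n_thresholds must lie in 1..4")
        if self.size_threshold_px <= 0:
            raise ProfileValidationError("size_threshold_px must be > 0")
        if self.edge_rule not in ("classify", "exclude"):
            raise ProfileValidationError("edge_rule must be 'classify' or 'exclude'")
        if self.connectivity not in (4, 8):
            raise ProfileValidationError("connectivity must be 4 or 8")


def capture_background(dark_frame: Frame, mode: str = "image") -> BackgroundCorrection:
    """Background correction from a dark (black-box) frame.

    ``mode="image"`` keeps the full per-pixel channel arrays; ``mode="scalar"``
    collapses each channel to its mean.
    """
    if mode == "scalar":
        return BackgroundCorrection(
            rc=float(dark_frame.red.mean()),
            gc=float(dark_frame.green.mean()),
            bc=float(dark_frame.blue.mean()),
        )
    if mode == "image":
        return BackgroundCorrection(
            rc=dark_frame.red.astype(float),
            gc=dark_frame.green.astype(float),
            bc=dark_frame.blue.astype(float),
        )
    raise ValueError("mode must be 'image' or 'scalar'")


# ----------------------------------------------------------------------------
# YAML serialisation


def _profile_to_dict(p: CalibrationProfile) -> dict:
    def bg_field(v):
        return v.tolist() if isinstance(v, np.ndarray) else float(v)

    return {
        "schema_version": SCHEMA_VERSION,
        "name": p.name,
        "created": p.created,
        "weights": {
            "alpha": p.weights.alpha,
            "beta": p.weights.beta,
            "gamma": p.weights.gamma,
            "L": p.weights.L,
            "red_correction_sign": p.weights.red_correction_sign,
        },
        "background": {
            "rc": bg_field(p.background.rc),
            "gc": bg_field(p.background.gc),
            "bc": bg_field(p.background.bc),
        },
        "segmentation": {
            "n_thresholds": p.n_thresholds,
            "vegetation_classes": list(p.vegetation_classes)
            if p.vegetation_classes is not None
            else None,
            "min_object_area": p.min_object_area,
            "connectivity": p.connectivity,
        },
        "classification": {
            "size_threshold_px": p.size_threshold_px,
            "edge_rule": p.edge_rule,
        },
        "zones": {
            "ignore_radius_mm": p.zones.ignore_radius_mm,
            "caution_radius_mm": p.zones.caution_radius_mm,
            "band_margin_px": p.zones.band_margin_px,
            "target_diameter_mm": p.zones.target_diameter_mm,
            "zone_assignment": p.zones.zone_assignment,
            "zone_reference": p.zones.zone_reference,
        },
        "geometry": {
            "height_mm": p.geometry.height_mm,
            "frame_width_px": p.geometry.frame_width_px,
            "frame_height_px": p.geometry.frame_height_px,
            "fov_mm": p.geometry.fov_mm,
            "px_per_mm": p.geometry.px_per_mm,
            "focal_px": p.geometry.focal_px,
        },
        "stereo": {
            "baseline_mm": p.stereo.baseline_mm,
            "frame_interval_s": p.stereo.frame_interval_s,
            "speed_mm_s": p.stereo.speed_mm_s,
            "laplacian_weight": p.stereo.laplacian_weight,
            "flow_params": dict(p.stereo.flow_params),
        },
        "channel_mix": p.mix.matrix.tolist(),
        "illumination": {
            "red": p.illum.red,
            "nir": p.illum.nir,
            "green": p.illum.green,
        },
    }


_REQUIRED_KEYS = {
    "schema_version",
    "weights",
    "background",
    "segmentation",
    "classification",
    "zones",
    "geometry",
    "stereo",
    "channel_mix",
    "illumination",
}
_OPTIONAL_KEYS = {"name", "created"}


def _profile_from_dict(d: dict) -> CalibrationProfile:
    if not isinstance(d, dict):
        raise ProfileValidationError("profile file must contain a mapping")
    unknown = set(d) - _REQUIRED_KEYS - _OPTIONAL_KEYS
    if unknown:
        raise ProfileValidationError(f"unknown profile keys: {sorted(unknown)}")
    missing = _REQUIRED_KEYS - set(d)
    if missing:
        raise ProfileValidationError(f"missing profile sections: {sorted(missing)}")
    if d["schema_version"] != SCHEMA_VERSION:
        raise ProfileValidationError(
            f"unsupported schema_version {d['schema_version']} (expected {SCHEMA_VERSION})"
        )

    def bg_field(v):
        return np.asarray(v, dtype=float) if isinstance(v, list) else float(v)

    try:
        weights = IndexWeights(**d["weights"])
        background = BackgroundCorrection(
            rc=bg_field(d["background"]["rc"]),
            gc=bg_field(d["background"]["gc"]),
            bc=bg_field(d["background"]["bc"]),
        )
        seg = d["segmentation"]
        zones = ZoneConfig(**d["zones"])
        geometry = CameraGeometry(**d["geometry"])
        stereo = StereoConfig(**d["stereo"])
        mix = ChannelMixMatrix(np.asarray(d["channel_mix"], dtype=float))
        illum = IlluminationConfig(**d["illumination"])
        vc = seg.get("vegetation_classes")
        return CalibrationProfile(
            weights=weights,
            background=background,
            n_thresholds=seg["n_thresholds"],
            vegetation_classes=tuple(vc) if vc is not None else None,
            min_object_area=seg["min_object_area"],
            connectivity=seg["connectivity"],
            size_threshold_px=d["classification"]["size_threshold_px"],
            edge_rule=d["classification"]["edge_rule"],
            zones=zones,
            geometry=geometry,
            stereo=stereo,
            mix=mix,
            illum=illum,
            name=d.get("name", "default"),
            created=d.get("created", ""),
        )
    except (TypeError, KeyError) as exc:
        raise ProfileValidationError(f"malformed profile: {exc}") from exc
    except ValueError as exc:
        raise ProfileValidationError(str(exc)) from exc


def save_profile(profile: CalibrationProfile, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_profile_to_dict(profile), fh, sort_keys=False)


def load_profile(path: str) -> CalibrationProfile:
    with open(path) as fh:
        try:
            d = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ProfileValidationError(f"malformed YAML in {path!r}: {exc}") from exc
    return _profile_from_dict(d)


# ----------------------------------------------------------------------------
# Offline tuning


def _score_profile(
    profile: CalibrationProfile,
    labelled_frames: list[tuple[Frame, pd.DataFrame]],
    match_radius_mm: float,
    weights: tuple[float, float],
) -> float:
    from .evaluation import match_detections
    from .pipeline import detect_frame

    scores = []
    for frame, truth in labelled_frames:
        result = detect_frame(frame, profile)
        det = result.detections_table()
        truth_plants = truth[truth["kind"].isin(["crop", "weed"])]
        if truth_plants.empty:
            scores.append(0.0)
            continue
        mr = match_detections(det, truth, match_radius_mm)
        crops = [t for t, k in mr.truth_kinds.items() if k == "crop"]
        weeds = [t for t, k in mr.truth_kinds.items() if k == "weed"]
        crop_recall = (
            sum(mr.truth_categories[t] == "crop" for t in crops) / len(crops)
            if crops
            else None
        )
        weed_recall = (
            sum(mr.truth_categories[t] in ("weed", "multiple") for t in weeds) / len(weeds)
            if weeds
            else None
        )
        parts, wts = [], []
        if weed_recall is not None:
            parts.append(weed_recall)
            wts.append(weights[0])
        if crop_recall is not None:
            parts.append(crop_recall)
            wts.append(weights[1])
        scores.append(float(np.average(parts, weights=wts)) if parts else 0.0)
    return float(np.mean(scores)) if scores else 0.0


def tune_profile(
    labelled_frames: list[tuple[Frame, pd.DataFrame]],
    search_space: dict[str, list],
    base_profile: CalibrationProfile | None = None,
    match_radius_mm: float = 20.0,
    objective_weights: tuple[float, float] = (1.0, 1.0),
) -> tuple[CalibrationProfile, float]:
    """Exhaustive grid search over index weights and the size threshold.

    ``search_space`` maps parameter names (``alpha``, ``beta``, ``gamma``,
    ``L``, ``size_threshold_px``) to candidate lists; unlisted parameters stay
    at the base profile's values.  The objective is the (configurable-weight)
    mean of weed recall and crop recall averaged over the labelled frames;
    ties go to the first-best tuple in grid order, so tuning is deterministic.
    """
    if not labelled_frames:
        raise ValueError("at least one labelled frame is required")
    allowed = {"alpha", "beta", "gamma", "L", "size_threshold_px"}
    bad = set(search_space) - allowed
    if bad:
        raise ValueError(f"unknown tuning parameters: {sorted(bad)}")
    keys = list(search_space)
    grids = [search_space[k] for k in keys]
    if not keys or any(len(g) == 0 for g in grids):
        raise ValueError("search space grid is empty")
    base = base_profile or CalibrationProfile()

    best: tuple[CalibrationProfile, float] | None = None
    for combo in itertools.product(*grids):
        params = dict(zip(keys, combo))
        w = replace(
            base.weights,
            alpha=params.get("alpha", base.weights.alpha),
            beta=params.get("beta", base.weights.beta),
            gamma=params.get("gamma", base.weights.gamma),
            L=params.get("L", base.weights.L),
        )
        cand = replace(
            base,
            weights=w,
            size_threshold_px=int(params.get("size_threshold_px", base.size_threshold_px)),
        )
        score = _score_profile(cand, labelled_frames, match_radius_mm, objective_weights)
        if best is None or score > best[1]:
            best = (cand, score)
    return best
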