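"""Synthetic field scenes with known ground truth, rendered through the same
spectral channel-mixing model the detection pipeline inverts.

A scene is a soil plane plus crop / weed / debris objects, each with a ground
position, a height and a band reflectance triple at (650, 850, 525) nm.  The
renderer composes per-pixel band reflectances (objects over soil, later
objects over earlier), applies the effective channel response (quantum
efficiency x LED duty cycle), adds soil texture and sensor noise, and clips
to 8 bits.  A raised object is drawn at its parallax-displaced apparent
position — offset from the camera nadir magnified by H / (H - h) — so frame
pairs rendered at two camera offsets exercise the kinematic-stereo model
end to end.

Soil texture is anchored in ground coordinates (it translates with the ground
between frames) and is spectrally non-uniform, so the RGNIR index of bare
soil carries the smooth trackable texture a dense flow estimator needs.
Object texture lives in object-local coordinates and moves with the object.

Default reflectance priors mimic generic leaf and dry-soil optics under
narrow-band illumination: vegetation low at 650 nm, high at 850 nm and
fairly bright at 525 nm; soil a flat, slowly rising spectrum; debris soil-like
with jitter.  All priors are configurable per scene.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import ndimage

from .imaging import (
    CameraGeometry,
    ChannelMixMatrix,
    Frame,
    IlluminationConfig,
    effective_response,
)

__all__ = ["SceneObject", "SceneSpec", "random_scene", "render_frame", "render_pair", "ground_truth"]

# band order (650, 850, 525) nm
VEG_REFLECTANCE = (0.05, 0.45, 0.35)
SOIL_REFLECTANCE = (0.28, 0.32, 0.24)
DEBRIS_REFLECTANCE = (0.31, 0.34, 0.27)
# per-band soil texture amplitudes; spectrally non-uniform so the texture
# survives the normalised index
SOIL_TEXTURE_BAND_GAIN = (2.0, 0.2, 1.0)


@dataclass
class SceneObject:
    """One crop, weed or debris object on the ground plane."""

    kind: str  # crop | weed | debris
    centre_mm: tuple[float, float]  # (x along travel, y across)
    equivalent_radius_mm: float
    height_mm: float = 0.0
    reflectance: tuple[float, float, float] = VEG_REFLECTANCE
    shape: dict = field(default_factory=lambda: {"kind": "disc"})

    def __post_init__(self) -> None:
        if self.kind not in ("crop", "weed", "debris"):
            raise ValueError(f"unknown object kind {self.kind!r}")
        if self.equivalent_radius_mm <= 0:
            raise ValueError("equivalent_radius_mm must be > 0")
        if not (0.0 <= self.height_mm <= 200.0):
            raise ValueError("height_mm must lie in [0, 200]")
        if any(not (0.0 <= r <= 1.0) for r in self.reflectance):
            raise ValueError("reflectance entries must lie in [0, 1]")


@dataclass
class SceneSpec:
    """Ground-truth description of one synthetic field scene.

    Identical spec + seed renders bit-identically.
    """

    objects: list[SceneObject] = field(default_factory=list)
    soil_reflectance: tuple[float, float, float] = SOIL_REFLECTANCE
    soil_texture_amplitude: float = 0.15
    object_texture_amplitude: float = 0.15
    noise_sigma: float = 0.0  # additive Gaussian, 8-bit units
    seed: int = 0
    extent_mm: float = 540.0
    gain: float = 4.0  # exposure gain lifting signals into the 8-bit range

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SceneSpec":
        d = dict(d)
        d["objects"] = [SceneObject(**{**o, "centre_mm": tuple(o["centre_mm"]),
                                       "reflectance": tuple(o["reflectance"])})
                        for o in d.get("objects", [])]
        for key in ("soil_reflectance",):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], sigma: float) -> np.ndarray:
    """Zero-mean, unit-RMS band-limited noise field."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    rms = np.sqrt(np.mean(f**2))
    return f / rms if rms > 0 else f


def random_scene(
    density_weeds_per_m2: float,
    n_crops: int,
    seed: int,
    kind_params: dict | None = None,
) -> SceneSpec:
    """Draw a random scene emulating a lettuce bed.

    Crops sit on a regular along-track row with positional jitter; the weed
    count is Poisson(density x field area) with uniform positions.  Debris
    objects (stones, twigs) can be added via ``kind_params['n_debris']``.
    """
    if density_weeds_per_m2 < 0:
        raise ValueError("weed density must be >= 0")
    p = {
        "extent_mm": 540.0,
        "crop_radius_mm": (50.0, 65.0),
        "crop_height_mm": (20.0, 60.0),
        "crop_lobes": (3, 5),
        "weed_radius_mm": (5.0, 14.0),
        "weed_height_mm": (0.0, 30.0),
        "n_debris": 0,
        "debris_radius_mm": (4.0, 12.0),
        "reflectance_jitter": 0.08,
        "noise_sigma": 0.0,
        "min_separation_mm": 0.0,
        "edge_margin_mm": 0.0,
    }
    p.update(kind_params or {})
    rng = np.random.default_rng(seed)
    extent = p["extent_mm"]
    objects: list[SceneObject] = []

    def jittered_reflectance(base: tuple[float, float, float]) -> tuple[float, float, float]:
        j = 1.0 + p["reflectance_jitter"] * rng.uniform(-1, 1, size=3)
        return tuple(float(v) for v in np.clip(np.array(base) * j, 0.0, 1.0))

    if n_crops > 0:
        xs = (np.arange(n_crops) + 0.5) / n_crops * extent - extent / 2
        for x in xs:
            jitter = rng.uniform(-10, 10, size=2)
            r = rng.uniform(*p["crop_radius_mm"])
            lobes = int(rng.integers(p["crop_lobes"][0], p["crop_lobes"][1] + 1))
            objects.append(
                SceneObject(
                    kind="crop",
                    centre_mm=(float(x + jitter[0]), float(jitter[1])),
                    equivalent_radius_mm=float(r),
                    height_mm=float(rng.uniform(*p["crop_height_mm"])),
                    reflectance=jittered_reflectance(VEG_REFLECTANCE),
                    shape={
                        "kind": "rosette",
                        "lobes": lobes,
                        "lobe_radius_mm": 0.65 * r,
                        "lobe_offset_mm": 0.5 * r,
                        "phase": float(rng.uniform(0, 2 * np.pi)),
                    },
                )
            )
    def draw_position(radius: float) -> tuple[float, float] | None:
        """Uniform position respecting the edge margin and, when configured,
        a minimum clearance to already-placed objects (rejection sampling)."""
        lo = -extent / 2 + p["edge_margin_mm"]
        hi = extent / 2 - p["edge_margin_mm"]
        for _ in range(200):
            cand = rng.uniform(lo, hi, size=2)
            sep = p["min_separation_mm"]
            if not sep:
                return (float(cand[0]), float(cand[1]))
            clear = all(
                np.hypot(cand[0] - o.centre_mm[0], cand[1] - o.centre_mm[1])
                >= sep + radius + o.equivalent_radius_mm
                for o in objects
            )
            if clear:
                return (float(cand[0]), float(cand[1]))
        return None

    area_m2 = (extent / 1000.0) ** 2
    n_weeds = int(rng.poisson(density_weeds_per_m2 * area_m2))
    for _ in range(n_weeds):
        r = float(rng.uniform(*p["weed_radius_mm"]))
        pos = draw_position(r)
        if pos is None:
            continue
        objects.append(
            SceneObject(
                kind="weed",
                centre_mm=pos,
                equivalent_radius_mm=r,
                height_mm=float(rng.uniform(*p["weed_height_mm"])),
                reflectance=jittered_reflectance(VEG_REFLECTANCE),
            )
        )
    for _ in range(int(p["n_debris"])):
        r = float(rng.uniform(*p["debris_radius_mm"]))
        pos = draw_position(r)
        if pos is None:
            continue
        objects.append(
            SceneObject(
                kind="debris",
                centre_mm=pos,
                equivalent_radius_mm=r,
                reflectance=jittered_reflectance(DEBRIS_REFLECTANCE),
            )
        )
    return SceneSpec(
        objects=objects,
        seed=seed,
        extent_mm=extent,
        noise_sigma=p["noise_sigma"],
    )


def _object_mask(
    obj: SceneObject,
    rows_mm: np.ndarray,
    cols_mm: np.ndarray,
    centre: tuple[float, float],
    mag: float = 1.0,
) -> np.ndarray:
    """Boolean footprint of an object on the (x_mm, y_mm) pixel grids."""
    dx = rows_mm - centre[0]
    dy = cols_mm - centre[1]
    shape = obj.shape
    if shape.get("kind", "disc") == "rosette":
        lobes = shape["lobes"]
        lr = shape["lobe_radius_mm"] * mag
        lo = shape["lobe_offset_mm"] * mag
        phase = shape.get("phase", 0.0)
        mask = np.zeros(dx.shape, dtype=bool)
        for k in range(lobes):
            ang = phase + 2 * np.pi * k / lobes
            mask |= (dx - lo * np.cos(ang)) ** 2 + (dy - lo * np.sin(ang)) ** 2 <= lr**2
        return mask
    r = obj.equivalent_radius_mm * mag
    return dx**2 + dy**2 <= r**2


def _grids_mm(geom: CameraGeometry) -> tuple[np.ndarray, np.ndarray]:
    cr, cc = geom.centre_px
    x = (np.arange(geom.frame_height_px) - cr)[:, None] / geom.px_per_mm
    y = (np.arange(geom.frame_width_px) - cc)[None, :] / geom.px_per_mm
    return np.broadcast_to(x, (geom.frame_height_px, geom.frame_width_px)), np.broadcast_to(
        y, (geom.frame_height_px, geom.frame_width_px)
    )


_TEXTURE_MARGIN_MM = 64.0
_TEXTURE_SIGMA_MM = 3.0


def render_frame(
    scene: SceneSpec,
    geom: CameraGeometry,
    mix: ChannelMixMatrix | None = None,
    illum: IlluminationConfig | None = None,
    camera_offset_mm: float = 0.0,
    frame_index: int = 0,
    timestamp: float = 0.0,
) -> Frame:
    """Render one frame with the camera nadir displaced ``camera_offset_mm``
    along the direction of travel.

    Objects outside the imaged area are silently clipped.
    """
    mix = mix or ChannelMixMatrix()
    illum = illum or IlluminationConfig()
    E = effective_response(mix, illum)

    x_mm, y_mm = _grids_mm(geom)
    h_px, w_px = x_mm.shape

    # --- soil, textured in ground coordinates ---------------------------------
    ss = np.random.SeedSequence(entropy=scene.seed)
    soil_rng = np.random.default_rng(ss.spawn(1)[0])
    n_tex = int(np.ceil(scene.extent_mm + 2 * _TEXTURE_MARGIN_MM)) + 2
    tex = _smooth_field(soil_rng, (n_tex, n_tex), _TEXTURE_SIGMA_MM)
    gx = x_mm + camera_offset_mm + scene.extent_mm / 2 + _TEXTURE_MARGIN_MM
    gy = y_mm + scene.extent_mm / 2 + _TEXTURE_MARGIN_MM
    soil_tex = ndimage.map_coordinates(tex, [gx, gy], order=3, mode="nearest")

    refl = np.empty((3, h_px, w_px))
    for b in range(3):
        mod = 1.0 + scene.soil_texture_amplitude * SOIL_TEXTURE_BAND_GAIN[b] * soil_tex
        refl[b] = scene.soil_reflectance[b] * np.clip(mod, 0.0, None)

    # --- objects at their parallax-displaced apparent positions --------------
    H = geom.height_mm
    obj_seeds = np.random.SeedSequence(entropy=scene.seed).spawn(len(scene.objects) + 2)
    for i, obj in enumerate(scene.objects):
        mag = H / (H - obj.height_mm)
        app = (
            (obj.centre_mm[0] - camera_offset_mm) * mag,
            obj.centre_mm[1] * mag,
        )
        mask = _object_mask(obj, x_mm, y_mm, app, mag=mag)
        if not mask.any():
            continue
        # object-local texture: anchored to the object, identical in both
        # frames of a pair up to the apparent shift
        orng = np.random.default_rng(obj_seeds[i + 2])
        n_loc = int(np.ceil(4 * obj.equivalent_radius_mm * mag)) + 8
        ltex = _smooth_field(orng, (n_loc, n_loc), _TEXTURE_SIGMA_MM)
        rr, cc = np.nonzero(mask)
        sl = (slice(rr.min(), rr.max() + 1), slice(cc.min(), cc.max() + 1))
        lx = (x_mm[sl] - app[0]) + n_loc / 2
        ly = (y_mm[sl] - app[1]) + n_loc / 2
        local = ndimage.map_coordinates(ltex, [lx, ly], order=3, mode="nearest")
        sub = mask[sl]
        for b in range(3):
            band_gain = SOIL_TEXTURE_BAND_GAIN[b]
            mod = 1.0 + scene.object_texture_amplitude * band_gain * local
            refl[b][sl][sub] = obj.reflectance[b] * np.clip(mod, 0.0, None)[sub]

    # --- spectral mixing and sensor model -------------------------------------
    signal = scene.gain * 255.0 * np.einsum("cb,bhw->chw", E, refl)
    if scene.noise_sigma > 0:
        noise_rng = np.random.default_rng(
            np.random.SeedSequence(
                entropy=scene.seed,
                spawn_key=(int(round(abs(camera_offset_mm) * 1000)) + 1,),
            )
        )
        signal = signal + noise_rng.normal(0, scene.noise_sigma, size=signal.shape)
    img = np.clip(np.floor(signal + 0.5), 0, 255).astype(np.uint8)
    return Frame(
        red=img[0], green=img[1], blue=img[2], timestamp=timestamp, index=frame_index
    )


def render_pair(
    scene: SceneSpec,
    geom: CameraGeometry,
    mix: ChannelMixMatrix | None = None,
    illum: IlluminationConfig | None = None,
    baseline_mm: float = 21.0,
    frame_index: int = 0,
    timestamp: float = 0.0,
    frame_interval_s: float = 1 / 90.0,
) -> tuple[Frame, Frame]:
    """Render a kinematic-stereo pair: camera offsets 0 and ``baseline_mm``.

    Ground pixels shift by ``baseline * px_per_mm``; raised objects shift more
    by the factor H / (H - h).
    """
    if baseline_mm < 0:
        raise ValueError("baseline must be >= 0")
    f0 = render_frame(scene, geom, mix, illum, 0.0, frame_index, timestamp)
    f1 = render_frame(
        scene, geom, mix, illum, baseline_mm, frame_index + 1, timestamp + frame_interval_s
    )
    return f0, f1


def ground_truth(
    scene: SceneSpec,
    geom: CameraGeometry,
    frame_window: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Reference table of true objects for the evaluation module.

    Pixel positions and areas are parallax-free (camera at offset 0, heights
    ignored for the footprint).  Objects whose centre falls outside the frame
    window (``(row_min, row_max)``, default the full frame) are excluded.
    """
    x_mm, y_mm = _grids_mm(geom)
    rows = []
    lo, hi = frame_window if frame_window else (0, geom.frame_height_px)
    for i, obj in enumerate(scene.objects):
        r_px, c_px = geom.ground_mm_to_px(*obj.centre_mm)
        if not (lo <= r_px < hi and 0 <= c_px < geom.frame_width_px):
            continue
        area_px = int(_object_mask(obj, x_mm, y_mm, obj.centre_mm).sum())
        rows.append(
            {
                "object": i,
                "kind": obj.kind,
                "x_mm": obj.centre_mm[0],
                "y_mm": obj.centre_mm[1],
                "row_px": r_px,
                "col_px": c_px,
                "area_px": area_px,
                "equivalent_radius_mm": obj.equivalent_radius_mm,
                "height_mm": obj.height_mm,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "object",
            "kind",
            "x_mm",
            "y_mm",
            "row_px",
            "col_px",
            "area_px",
            "equivalent_radius_mm",
            "height_mm",
        ],
    )
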