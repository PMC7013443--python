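import numpy as np
import pytest

from weedseg import CalibrationProfile, CameraGeometry


@pytest.fixture
def small_geom() -> CameraGeometry:
    """Quarter-size frame at the production ground resolution (~0.948 px/mm)."""
    return CameraGeometry(frame_width_px=256, frame_height_px=256, fov_mm=270.0)


@pytest.fixture
def small_profile(small_geom) -> CalibrationProfile:
    return CalibrationProfile(geometry=small_geom, size_threshold_px=2000)


# scene parameters giving size-separable, non-overlapping objects on the
# quarter-size frame: weed radius <= 15 mm, crop radius >= 50 mm, and the
# 2000 px^2 threshold sits between the resulting areas
SEPARABLE_KIND_PARAMS = {
    "extent_mm": 270.0,
    "crop_radius_mm": (50.0, 60.0),
    "weed_radius_mm": (6.0, 15.0),
    "crop_height_mm": (0.0, 0.0),
    "weed_height_mm": (0.0, 0.0),
    "min_separation_mm": 15.0,
    "edge_margin_mm": 25.0,
}


@pytest.fixture
def separable_kind_params() -> dict:
    return dict(SEPARABLE_KIND_PARAMS)


def naive_otsu_oracle(hist: np.ndarray, n_thresholds: int) -> tuple[tuple[int, ...], float]:
    """Independent exhaustive multi-Otsu: class statistics by direct slice
    summation (no prefix sums), full enumeration of increasing tuples.

    Returns (lexicographically smallest argmax, max objective) where the
    objective is sum_k M_k^2 / W_k, equivalent to between-class variance up
    to a constant.
    """
    h = np.asarray(hist, dtype=np.int64)
    idx = np.arange(256, dtype=np.int64)
    S = np.zeros((256, 256))
    for lo in range(256):
        for hi in range(lo, 256):
            w = int(h[lo : hi + 1].sum())
            if w:
                m = int((idx[lo : hi + 1] * h[lo : hi + 1]).sum())
                S[lo, hi] = m * m / w
    t = np.arange(255)
    if n_thresholds == 1:
        total = S[0, t] + S[t + 1, 255]
        best = int(np.argmax(total))
        return (best,), float(total[best])
    if n_thresholds == 2:
        total = S[0, t][:, None] + S[t + 1, :][:, t] + S[t + 1, 255][None, :]
        total = np.where(t[None, :] > t[:, None], total, -np.inf)
        flat = int(np.argmax(total))
        return (flat // 255, flat % 255), float(total.flat[flat])
    if n_thresholds == 3:
        pair = S[t[:, None] + 1, t[None, :]]  # class (t_a, t_b]
        total = (
            S[0, t][:, None, None]
            + pair[:, :, None]
            + pair[None, :, :]
            + S[t + 1, 255][None, None, :]
        )
        t1 = t[:, None, None]
        t2 = t[None, :, None]
        t3 = t[None, None, :]
        total = np.where((t2 > t1) & (t3 > t2), total, -np.inf)
        flat = int(np.argmax(total))
        return (
            (flat // (255 * 255), (flat // 255) % 255, flat % 255),
            float(total.flat[flat]),
        )
    raise ValueError("oracle supports 1-3 thresholds")
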