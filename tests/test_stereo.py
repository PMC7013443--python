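import numpy as np
import pytest
from scipy.ndimage import gaussian_filter, shift as ndshift

from weedseg import (
    CameraGeometry,
    FlowField,
    StereoConfig,
    dense_flow,
    disparity_to_height,
    enhance_texture,
    estimate_baseline,
    object_height,
    parallax_correct,
    parallax_error_map,
)
from weedseg.stereo import InvalidDisparityError
from weedseg.objects import PlantObject


def _textured(shape=(128, 128), seed=0):
    rng = np.random.default_rng(seed)
    img = gaussian_filter(rng.normal(size=shape), 2.0)
    return (img - img.min()) / np.ptp(img)


class TestEnhanceTexture:
    def test_constant_image_unchanged(self):
        img = np.full((16, 16), 7.0)
        np.testing.assert_allclose(enhance_texture(img, 1.0), img)

    def test_zero_weight_is_identity(self):
        img = _textured((32, 32))
        np.testing.assert_allclose(enhance_texture(img, 0.0), img)

    def test_single_bright_pixel_hand_convolution(self):
        img = np.zeros((5, 5))
        img[2, 2] = 10.0
        out = enhance_texture(img, 1.0)
        # centre: 10 + (-4*10) = -30, clipped to input min 0
        assert out[2, 2] == 0.0
        # 4-neighbours: 0 + 1*10 = 10
        for r, c in [(1, 2), (3, 2), (2, 1), (2, 3)]:
            assert out[r, c] == 10.0

    def test_laplacian_energy_increases_on_sharp_featured_images(self):
        """Enhancement boosts high-spatial-frequency energy on images with
        fine detail (sensor noise, object edges) — the regime it is meant for.
        Strongly band-limited images are excluded: a field with no energy at
        the amplified frequencies can lose Laplacian variance instead."""
        from scipy.ndimage import convolve
        from weedseg.stereo import LAPLACIAN_KERNEL

        rng = np.random.default_rng(0)
        discs = np.zeros((128, 128))
        rr, cc = np.mgrid[:128, :128]
        discs[(rr - 40) ** 2 + (cc - 50) ** 2 < 400] = 1.0
        discs[(rr - 90) ** 2 + (cc - 90) ** 2 < 100] = 0.7
        images = [
            rng.normal(size=(128, 128)),
            gaussian_filter(rng.normal(size=(128, 128)), 1.0),
            discs,
        ]
        for img in images:
            out = enhance_texture(img, 1.0)
            lap_in = convolve(img, LAPLACIAN_KERNEL, mode="nearest")
            lap_out = convolve(out, LAPLACIAN_KERNEL, mode="nearest")
            assert lap_out.var() > lap_in.var()


class TestDenseFlow:
    def test_identical_frames_give_zero_flow(self):
        img = _textured()
        flow = dense_flow(img, img)
        assert np.median(np.abs(flow.d_along)) < 0.1
        assert np.median(np.abs(flow.d_cross)) < 0.1

    @pytest.mark.parametrize("k", [2, 5, 12, 20])
    def test_pure_translation_recovered(self, k):
        img = _textured((192, 192))
        moved = ndshift(img, (k, 0), order=3, mode="nearest")
        flow = dense_flow(img, moved)
        assert abs(np.median(flow.d_along) - k) < 0.5

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="shapes differ"):
            dense_flow(np.zeros((4, 4)), np.zeros((5, 5)))


class TestDisparityToHeight:
    def geom(self):
        return CameraGeometry()

    def test_ground_plane_closed_form(self):
        geom, cfg = self.geom(), StereoConfig()
        d_ground = cfg.baseline_mm * geom.focal_px / geom.height_mm
        assert disparity_to_height(d_ground, cfg, geom) == pytest.approx(0.0)

    def test_hand_evaluated_example(self):
        geom = CameraGeometry(height_mm=600.0, focal_px=568.2)
        cfg = StereoConfig(baseline_mm=21.0)
        # Z = 21 * 568.2 / 21.33 = 559.4 mm -> height ~ 40.6 mm
        h = disparity_to_height(21.33, cfg, geom)
        assert h == pytest.approx(600.0 - 21.0 * 568.2 / 21.33)
        assert h == pytest.approx(40.6, abs=0.5)

    def test_infinite_disparity_clamps_to_camera_height(self):
        geom, cfg = self.geom(), StereoConfig()
        assert disparity_to_height(1e12, cfg, geom) == pytest.approx(geom.height_mm)

    def test_non_positive_disparity_rejected(self):
        with pytest.raises(InvalidDisparityError):
            disparity_to_height(0.0, StereoConfig(), self.geom())

    def test_round_trip_through_depth(self):
        geom, cfg = self.geom(), StereoConfig()
        for h in (0.0, 17.5, 99.0, 240.0):
            z = geom.height_mm - h
            d = cfg.baseline_mm * geom.focal_px / z
            assert disparity_to_height(d, cfg, geom) == pytest.approx(h, abs=1e-9)


class TestObjectHeight:
    def test_uniform_flow_field(self):
        geom, cfg = CameraGeometry(), StereoConfig()
        d_ground = cfg.baseline_mm * geom.focal_px / geom.height_mm
        flow = FlowField(
            d_along=np.full((64, 64), -d_ground), d_cross=np.zeros((64, 64))
        )
        obj = PlantObject(0, 50, (32.0, 32.0), (30, 30, 34, 34), False)
        assert object_height(flow, obj, cfg, geom) == pytest.approx(0.0, abs=1e-9)

    def test_corner_window_is_cropped(self):
        geom, cfg = CameraGeometry(), StereoConfig()
        flow = FlowField(d_along=np.full((32, 32), -20.0), d_cross=np.zeros((32, 32)))
        obj = PlantObject(0, 10, (0.0, 0.0), (0, 0, 2, 2), True)
        assert np.isfinite(object_height(flow, obj, cfg, geom))

    def test_centroid_outside_field(self):
        geom, cfg = CameraGeometry(), StereoConfig()
        flow = FlowField(d_along=np.zeros((16, 16)), d_cross=np.zeros((16, 16)))
        obj = PlantObject(0, 10, (100.0, 100.0), (99, 99, 101, 101), False)
        with pytest.raises(IndexError):
            object_height(flow, obj, cfg, geom)


class TestParallaxCorrect:
    def test_ground_plane_identity(self):
        geom = CameraGeometry()
        pos = (100.0, 400.0)
        x0, y0 = geom.px_to_ground_mm(*pos)
        assert parallax_correct(pos, 0.0, geom) == pytest.approx((x0, y0))

    def test_nadir_invariance(self):
        geom = CameraGeometry()
        assert parallax_correct(geom.centre_px, 123.0, geom) == pytest.approx((0.0, 0.0))

    def test_hand_evaluated_similar_triangles(self):
        # H = 600, h = 60, apparent offset 100 mm -> true offset 90 mm
        geom = CameraGeometry()
        r, c = geom.ground_mm_to_px(100.0, 0.0)
        x, y = parallax_correct((r, c), 60.0, geom)
        assert x == pytest.approx(90.0)
        assert y == pytest.approx(0.0)

    def test_reprojection_round_trip(self):
        geom = CameraGeometry()
        for h in (10.0, 60.0, 150.0):
            pos = (40.0, 500.0)
            x_t, y_t = parallax_correct(pos, h, geom)
            scale = geom.height_mm / (geom.height_mm - h)
            x_a, y_a = geom.px_to_ground_mm(*pos)
            assert (x_t * scale, y_t * scale) == pytest.approx((x_a, y_a))

    def test_height_above_camera_rejected(self):
        geom = CameraGeometry()
        with pytest.raises(ValueError, match="height"):
            parallax_correct((0.0, 0.0), 700.0, geom)


class TestParallaxErrorMap:
    def test_ground_plane_zero_everywhere(self):
        err, usable = parallax_error_map(CameraGeometry(), 0.0)
        assert not err.any()
        assert usable == 1.0

    def test_nadir_error_zero_for_any_height(self):
        geom = CameraGeometry()
        err, _ = parallax_error_map(geom, 150.0)
        cr, cc = geom.centre_px
        assert err[int(cr), int(cc)] == pytest.approx(0.0, abs=1e-2)

    def test_monotone_along_rays_from_nadir(self):
        geom = CameraGeometry()
        err, _ = parallax_error_map(geom, 100.0)
        cr, cc = int(geom.centre_px[0]), int(geom.centre_px[1])
        for ray in (err[cr, cc:], err[cr:, cc], np.diagonal(err[cr:, cc:])):
            assert np.all(np.diff(ray) >= -1e-12)

    def test_matches_closed_form(self):
        geom = CameraGeometry()
        h = 100.0
        err, _ = parallax_error_map(geom, h)
        r, c = geom.ground_mm_to_px(120.0, -80.0)
        expected = np.hypot(120.0, -80.0) * h / geom.height_mm / (geom.fov_mm / 2)
        assert err[int(round(r)), int(round(c))] == pytest.approx(expected, rel=0.05)


class TestEstimateBaseline:
    def test_from_uniform_ground_flow(self):
        geom = CameraGeometry()
        b_true = 21.0
        d = b_true * geom.focal_px / geom.height_mm
        flow = FlowField(d_along=np.full((64, 64), -d), d_cross=np.zeros((64, 64)))
        assert estimate_baseline(flow, geom, StereoConfig()) == pytest.approx(b_true)

    def test_zero_flow_means_stationary(self):
        geom = CameraGeometry()
        flow = FlowField(d_along=np.zeros((8, 8)), d_cross=np.zeros((8, 8)))
        assert estimate_baseline(flow, geom, StereoConfig()) == 0.0

    def test_speed_interval_fallback(self):
        cfg = StereoConfig(baseline_mm=20.8, speed_mm_s=1389.0, frame_interval_s=0.015)
        assert estimate_baseline(None, CameraGeometry(), cfg) == pytest.approx(20.835)

    def test_empty_ground_mask_rejected(self):
        geom = CameraGeometry()
        flow = FlowField(d_along=np.zeros((8, 8)), d_cross=np.zeros((8, 8)))
        with pytest.raises(ValueError, match="ground"):
            estimate_baseline(flow, geom, StereoConfig(), ground_mask=np.zeros((8, 8), bool))

    def test_baseline_speed_consistency_check(self):
        with pytest.raises(ValueError, match="inconsistent"):
            StereoConfig(baseline_mm=21.0, speed_mm_s=1000.0, frame_interval_s=0.015)
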