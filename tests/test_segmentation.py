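import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from weedseg import (
    BackgroundCorrection,
    Frame,
    IndexImage,
    IndexWeights,
    compute_rgnir,
    multi_otsu,
    prefix_stats,
    quantise_index,
    vegetation_mask,
)
from weedseg.segmentation import DegenerateHistogramError, between_class_variance

from conftest import naive_otsu_oracle


def _frame(r, g, b):
    return Frame(
        red=np.asarray(r, np.uint8), green=np.asarray(g, np.uint8), blue=np.asarray(b, np.uint8)
    )


class TestComputeRgnir:
    def test_zero_numerator_gives_soil_constant(self):
        f = _frame(np.full((4, 4), 100), np.full((4, 4), 50), np.full((4, 4), 60))
        w = IndexWeights(L=0.3)
        out = compute_rgnir(f, BackgroundCorrection(gc=50.0), w)
        np.testing.assert_allclose(out.values, 0.3)

    def test_hand_computed_pixel(self):
        # Rc=100, Gc=150, Bc=60 with corrections (0, 50, 10), unit weights:
        # 100 / (100 + 100 + 50) = 0.4
        f = _frame([[100]], [[150]], [[60]])
        out = compute_rgnir(f, BackgroundCorrection(rc=0.0, gc=50.0, bc=10.0), IndexWeights())
        assert out.values[0, 0] == pytest.approx(0.4)

    def test_green_only_limit_is_unity(self):
        # alpha = gamma = 0, L = 0: numerator equals denominator where Gc > gc
        rng = np.random.default_rng(1)
        g = rng.integers(60, 250, (8, 8))
        f = _frame(rng.integers(0, 255, (8, 8)), g, rng.integers(0, 255, (8, 8)))
        out = compute_rgnir(
            f, BackgroundCorrection(gc=10.0), IndexWeights(alpha=0, beta=1, gamma=0, L=0)
        )
        np.testing.assert_allclose(out.values, 1.0)

    def test_zero_denominator_falls_back_to_L(self):
        f = _frame([[0]], [[0]], [[0]])
        out = compute_rgnir(f, BackgroundCorrection(), IndexWeights(L=0.7))
        assert out.values[0, 0] == 0.7

    def test_red_correction_sign_flag(self):
        f = _frame([[100]], [[150]], [[60]])
        bg = BackgroundCorrection(rc=20.0, gc=50.0, bc=10.0)
        plus = compute_rgnir(f, bg, IndexWeights(red_correction_sign="plus"))
        minus = compute_rgnir(f, bg, IndexWeights(red_correction_sign="minus"))
        assert plus.values[0, 0] == pytest.approx(100 / (120 + 100 + 50))
        assert minus.values[0, 0] == pytest.approx(100 / (80 + 100 + 50))

    def test_background_shape_mismatch(self):
        f = _frame(np.zeros((4, 4)), np.zeros((4, 4)), np.zeros((4, 4)))
        with pytest.raises(ValueError, match="shape"):
            compute_rgnir(f, BackgroundCorrection(gc=np.zeros((2, 2))), IndexWeights())

    def test_weight_bounds(self):
        with pytest.raises(ValueError, match="alpha"):
            IndexWeights(alpha=1.5)


class TestQuantise:
    def test_constant_image_single_bin(self):
        q, hist = quantise_index(IndexImage(np.full((8, 8), 0.37)))
        assert hist[0] == 64 and hist[1:].sum() == 0
        assert not q.any()

    def test_two_point_symmetry(self):
        v = np.zeros((4, 4))
        v[:2] = 1.0
        _, hist = quantise_index(IndexImage(v))
        assert hist[0] == 8 and hist[255] == 8

    def test_count_conservation(self):
        rng = np.random.default_rng(2)
        _, hist = quantise_index(IndexImage(rng.normal(size=(64, 64))))
        assert hist.sum() == 64 * 64

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            IndexImage(np.array([[np.inf]]))


class TestPrefixStats:
    def test_single_bin_mass(self):
        hist = np.zeros(256, np.int64)
        hist[3] = 5
        counts, moments = prefix_stats(hist)
        assert counts[2] == 0 and counts[3] == 5 and counts[255] == 5
        assert moments[2] == 0 and moments[3] == 15 and moments[255] == 15

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_matches_naive_double_loop(self, seed):
        rng = np.random.default_rng(seed)
        hist = rng.integers(0, 1000, 256).astype(np.int64)
        counts, moments = prefix_stats(hist)
        naive_c = np.array([sum(hist[: k + 1]) for k in range(256)])
        naive_m = np.array([sum(i * hist[i] for i in range(k + 1)) for k in range(256)])
        np.testing.assert_array_equal(counts, naive_c)
        np.testing.assert_array_equal(moments, naive_m)
        assert counts[-1] == hist.sum()


class TestMultiOtsu:
    def test_two_delta_masses(self):
        hist = np.zeros(256, np.int64)
        hist[50] = hist[200] = 100
        # any t in [50, 199] separates; smallest maximiser wins
        assert multi_otsu(hist, 1) == (50,)

    def test_three_delta_masses(self):
        hist = np.zeros(256, np.int64)
        hist[30] = hist[120] = hist[220] = 50
        assert multi_otsu(hist, 2) == (30, 120)

    def test_single_bin_degenerate(self):
        hist = np.zeros(256, np.int64)
        hist[7] = 1000
        with pytest.raises(DegenerateHistogramError):
            multi_otsu(hist, 1)

    def test_permutation_invariance_of_image_pixels(self):
        rng = np.random.default_rng(3)
        img = rng.integers(0, 256, (32, 32), np.uint8)
        hist = np.bincount(img.ravel(), minlength=256).astype(np.int64)
        shuffled = img.ravel().copy()
        rng.shuffle(shuffled)
        hist2 = np.bincount(shuffled, minlength=256).astype(np.int64)
        assert multi_otsu(hist, 2) == multi_otsu(hist2, 2)

    @pytest.mark.parametrize("n_thresholds", [1, 2, 3])
    @pytest.mark.parametrize("seed", range(8))
    def test_agrees_with_naive_exhaustive_oracle(self, n_thresholds, seed):
        rng = np.random.default_rng(100 * n_thresholds + seed)
        hist = rng.integers(0, 50, 256).astype(np.int64)
        got = multi_otsu(hist, n_thresholds)
        want, best_score = naive_otsu_oracle(hist, n_thresholds)
        assert got == want
        assert between_class_variance(hist, got) == pytest.approx(
            between_class_variance(hist, want)
        )

    def test_variance_dominates_all_tuples_from_oracle(self):
        """The returned tuple's between-class variance bounds every candidate."""
        rng = np.random.default_rng(42)
        hist = rng.integers(0, 30, 256).astype(np.int64)
        t = multi_otsu(hist, 1)
        best = between_class_variance(hist, t)
        for cand in range(255):
            assert best >= between_class_variance(hist, (cand,)) - 1e-9

    def test_crosscheck_against_skimage_on_bimodal(self):
        """On a well-separated bimodal image, an independent multi-Otsu
        implementation finds a threshold in the same inter-mode gap."""
        from skimage.filters import threshold_multiotsu

        rng = np.random.default_rng(5)
        img = np.concatenate(
            [rng.integers(30, 60, 2000), rng.integers(180, 220, 2000)]
        ).astype(np.uint8)
        hist = np.bincount(img, minlength=256).astype(np.int64)
        ours = multi_otsu(hist, 1)[0]
        theirs = threshold_multiotsu(img.reshape(40, 100), classes=2)[0]
        assert 59 <= ours < 180 and 59 <= theirs <= 180

    def test_bad_n_thresholds(self):
        hist = np.ones(256, np.int64)
        with pytest.raises(ValueError):
            multi_otsu(hist, 0)
        with pytest.raises(ValueError):
            multi_otsu(hist, 5)


class TestVegetationMask:
    def test_class_boundary_convention(self):
        q = np.array([[150, 100]], np.uint8)
        mask = vegetation_mask(q, (100,), {1})
        assert mask[0, 0] and not mask[0, 1]  # class 0 is [0, t1] inclusive

    def test_all_classes_gives_full_mask(self):
        q = np.arange(256, dtype=np.uint8).reshape(16, 16)
        assert vegetation_mask(q, (80, 170), {0, 1, 2}).all()

    def test_bright_discs_on_dark_soil(self):
        img = np.full((64, 64), 40, np.uint8)
        rr, cc = np.mgrid[:64, :64]
        discs = ((rr - 16) ** 2 + (cc - 16) ** 2 <= 36) | (
            (rr - 48) ** 2 + (cc - 40) ** 2 <= 25
        )
        img[discs] = 220
        hist = np.bincount(img.ravel(), minlength=256).astype(np.int64)
        t = multi_otsu(hist, 1)
        mask = vegetation_mask(img, t, {1})
        np.testing.assert_array_equal(mask, discs)

    def test_invalid_class_index(self):
        with pytest.raises(ValueError, match="class"):
            vegetation_mask(np.zeros((2, 2), np.uint8), (100,), {5})


class TestSelectVegetationClasses:
    def _hist(self, spec):
        h = np.zeros(256, np.int64)
        for centre, width, count in spec:
            h[centre - width : centre + width + 1] = count
        return h

    def test_soil_split_keeps_top_class_only(self):
        from weedseg.segmentation import select_vegetation_classes

        # dark soil, bright soil, vegetation: widest mean gap before the top class
        h = self._hist([(40, 8, 500), (90, 8, 500), (220, 5, 80)])
        t = multi_otsu(h, 2)
        assert select_vegetation_classes(h, t) == {2}

    def test_vegetation_split_keeps_both_bright_classes(self):
        from weedseg.segmentation import select_vegetation_classes

        # soil, vegetation-low, vegetation-high: widest gap after class 0
        h = self._hist([(50, 10, 800), (190, 6, 60), (225, 6, 60)])
        t = multi_otsu(h, 2)
        assert select_vegetation_classes(h, t) == {1, 2}
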