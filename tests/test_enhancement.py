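"""Contrast-enhancement chain: histogram, lesion band, gain passes, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis.extra import numpy as hnp

from lesionkit import enhancement, fixtures
from lesionkit.enhancement import (
    apply_gain_passes, compute_histogram, enhance, fuse_with_original,
    image_variance, locate_lesion_range, otsu_between_class_variance,
    otsu_threshold_from_histogram, weight_and_equalize_patch,
)


class TestHistogram:
    def test_single_level_image(self):
        img = np.full((10, 10), 42, dtype=np.uint8)
        hist = compute_histogram(img)
        assert hist.counts[42] == 100
        assert hist.counts.sum() == 100

    def test_matches_naive_tally_on_all_levels(self):
        img = np.arange(16, dtype=np.uint8).reshape(4, 4)
        hist = compute_histogram(img)
        naive = np.zeros(256, dtype=int)
        for v in img.ravel():
            naive[v] += 1
        assert np.array_equal(hist.counts, naive)

    @settings(max_examples=25, deadline=None)
    @given(hnp.arrays(np.uint8, (8, 9)))
    def test_counts_conserve_pixel_count(self, img):
        assert compute_histogram(img).counts.sum() == img.size

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError):
            compute_histogram(np.zeros((0, 0), dtype=np.uint8))


class TestLesionRange:
    def test_bimodal_split_matches_brute_force_otsu(self):
        img = np.concatenate([np.full(50, 40), np.full(50, 200)]).astype(np.uint8)
        img = img.reshape(10, 10)
        hist = compute_histogram(img)
        # exhaustive between-class variance search over all 256 thresholds
        counts = hist.counts.astype(float)
        levels = np.arange(256.0)
        best_t, best_v = -1, -1.0
        for t in range(256):
            w0 = counts[:t + 1].sum()
            w1 = counts[t + 1:].sum()
            if w0 == 0 or w1 == 0:
                continue
            mu0 = (counts[:t + 1] * levels[:t + 1]).sum() / w0
            mu1 = (counts[t + 1:] * levels[t + 1:]).sum() / w1
            v = w0 * w1 * (mu0 - mu1) ** 2
            if v > best_v:
                best_t, best_v = t, v
        rng_ = locate_lesion_range(hist, img)
        assert rng_.k1 == 40
        assert rng_.kn == best_t == otsu_threshold_from_histogram(hist.counts)
        assert rng_.patch_mask.sum() == 50

    def test_constant_image_degenerate(self):
        img = np.full((6, 6), 99, dtype=np.uint8)
        rng_ = locate_lesion_range(compute_histogram(img), img)
        assert rng_.degenerate
        assert rng_.patch_mask.all()

    def test_patch_overlaps_true_lesion(self):
        spec = fixtures.LesionImageSpec(height=128, width=128, center=(64, 64),
                                        axes=(30, 20), lesion_contrast=0.4, seed=7)
        img, mask = fixtures.generate_lesion_image(spec)
        gray = enhancement.to_gray(img)
        rng_ = locate_lesion_range(compute_histogram(gray), gray)
        inter = np.sum((rng_.patch_mask > 0) & (mask > 0))
        union = np.sum((rng_.patch_mask > 0) | (mask > 0))
        assert inter / union > 0.5


class TestVariance:
    def test_two_pixel_closed_form(self):
        img = np.array([[0], [255]], dtype=np.uint8)
        sigma2, mu = image_variance(img)
        assert mu == pytest.approx(127.5)
        assert sigma2 == pytest.approx(16256.25)

    def test_constant_image_zero_variance(self):
        sigma2, _ = image_variance(np.full((5, 5), 7, dtype=np.uint8))
        assert sigma2 == 0.0

    def test_matches_two_pass_loop(self, rng):
        img = rng.integers(0, 256, (32, 32)).astype(np.uint8)
        sigma2, mu = image_variance(img)
        vals = img.astype(float).ravel()
        mu_ref = sum(vals) / vals.size
        sigma2_ref = sum((v - mu_ref) ** 2 for v in vals) / vals.size
        assert mu == pytest.approx(mu_ref, rel=1e-9)
        assert sigma2 == pytest.approx(sigma2_ref, rel=1e-9)


class TestPatchEqualization:
    def test_constant_image_is_identity(self):
        img = np.full((8, 8), 120, dtype=np.uint8)
        rng_ = locate_lesion_range(compute_histogram(img), img)
        out = weight_and_equalize_patch(rng_, 0.0, img)
        assert np.array_equal(out, img)

    def test_two_level_patch_maps_to_range_extremes(self):
        # 60 pixels at 100, 40 at 140; in-patch equalization must map the
        # levels onto the extremes of the (amplified) patch range, matching
        # the hand-applied CDF formula.
        img = np.concatenate([np.full(60, 100), np.full(40, 140)]).astype(np.uint8)
        img = img.reshape(10, 10)
        from lesionkit.enhancement import LesionRange
        rng_ = LesionRange(k1=0, kn=255, patch_mask=np.ones_like(img))
        sigma2, _ = image_variance(img)
        out = weight_and_equalize_patch(rng_, sigma2, img)
        # hand: amplification about the mean 116 with gain 1 + sigma2/max_var
        w = sigma2 / enhancement.MAX_VARIANCE_8BIT
        lo = round(116 + (1 + w) * (100 - 116))
        hi = round(116 + (1 + w) * (140 - 116))
        assert set(np.unique(out)) == {lo, hi}

    def test_full_image_patch_matches_textbook_equalization(self, rng):
        img = rng.integers(0, 256, (32, 32)).astype(np.uint8)
        from lesionkit.enhancement import LesionRange
        patch = LesionRange(k1=0, kn=255, patch_mask=np.ones_like(img))
        out = weight_and_equalize_patch(patch, 0.0, img)  # w=0: no amplification
        counts = np.bincount(img.ravel(), minlength=256).astype(float)
        cdf = np.cumsum(counts) / counts.sum()
        occ = np.flatnonzero(counts)
        lo, hi = occ[0], occ[-1]
        cdf_min = cdf[lo]
        expected = np.clip(np.round(
            lo + (cdf[img] - cdf_min) / (1 - cdf_min) * (hi - lo)), 0, 255)
        assert np.array_equal(out, expected.astype(np.uint8))


class TestFusion:
    def test_identity_patch(self):
        img = np.arange(64, dtype=np.uint8).reshape(8, 8)
        assert np.array_equal(fuse_with_original(img, img), img)

    def test_alpha_one_returns_original(self, rng):
        img = rng.integers(0, 256, (8, 8)).astype(np.uint8)
        patch = rng.integers(0, 256, (8, 8)).astype(np.uint8)
        assert np.array_equal(fuse_with_original(img, patch, alpha=1.0), img)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fuse_with_original(np.zeros((4, 4), np.uint8), np.zeros((5, 5), np.uint8))


class TestGainPasses:
    def test_constant_image_fixed_point(self):
        img = np.full((8, 8), 100, dtype=np.uint8)
        p1, p2 = apply_gain_passes(img)
        assert np.array_equal(p1, img)
        assert np.array_equal(p2, img)

    def test_two_level_image_picks_maximal_separation_gain(self):
        img = np.concatenate([np.full(32, 100), np.full(32, 150)]).astype(np.uint8)
        img = img.reshape(8, 8)
        p1, _ = apply_gain_passes(img)
        # enumerate all five candidates by hand: gain 5 about mean 125 maps
        # {100,150} -> {0, 250} (clipped), the maximal separation
        scores = []
        for g in range(1, 6):
            cand = np.clip(125 + g * (img.astype(float) - 125), 0, 255).astype(np.uint8)
            scores.append(otsu_between_class_variance(cand))
        assert np.argmax(scores) + 1 == 5
        assert set(np.unique(p1)) == {0, 250}


class TestEnhance:
    def test_constant_gray_image_unchanged(self):
        img = np.full((16, 16), 77, dtype=np.uint8)
        assert np.array_equal(enhance(img), img)

    @pytest.mark.parametrize("shape", [(16, 16), (33, 47), (20, 20, 3)])
    def test_shape_preserved(self, rng, shape):
        img = rng.integers(0, 256, shape).astype(np.uint8)
        assert enhance(img).shape == img.shape

    def test_deterministic(self, rng):
        img = rng.integers(0, 256, (24, 24, 3)).astype(np.uint8)
        assert np.array_equal(enhance(img), enhance(img.copy()))

    def test_range_safety_and_monotone_contrast_on_fixture_batch(self):
        """Output stays 8-bit and Otsu separability does not drop, per batch."""
        improved = 0
        n = 40
        for s in range(n):
            spec = fixtures.class_image_spec(s % 2, 2, 64, seed=1000 + s)
            img, _ = fixtures.generate_lesion_image(spec)
            out = enhance(img)
            assert out.dtype == np.uint8
            v_in = otsu_between_class_variance(enhancement.to_gray(img))
            v_out = otsu_between_class_variance(enhancement.to_gray(out))
            improved += v_out >= v_in
        assert improved >= 0.95 * n

    def test_lesion_region_sd_not_reduced_by_fusion(self):
        spec = fixtures.LesionImageSpec(height=128, width=128, center=(64, 64),
                                        axes=(30, 20), lesion_contrast=0.4, seed=7)
        img, mask = fixtures.generate_lesion_image(spec)
        gray = enhancement.to_gray(img)
        res = enhancement.enhance_gray(gray)
        assert res.fused[mask == 1].std() >= gray[mask == 1].std() - 1e-9
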