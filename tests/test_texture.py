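"""GLCM texture: quantization, co-occurrence, correlation, λ fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from conftest import pearson_over_pairs
from stromaquant.io import CalibratedImage
from stromaquant.texture import (
    CorrelationFit,
    TextureCurve,
    compute_glcm,
    correlation_curve,
    estimate_correlation_length,
    fit_correlation_length,
    glcm_correlation,
    quantize,
)


class TestQuantize:
    def test_binary_image_two_levels(self):
        img = np.array([[0.0, 1.0], [1.0, 0.0]])
        assert set(quantize(img, 2).ravel()) == {0, 1}

    def test_idempotent_on_level_image(self, rng):
        q = rng.integers(0, 8, (16, 16)).astype(np.int32)
        # make sure both extreme levels occur so the range is exact
        q[0, 0], q[0, 1] = 0, 7
        np.testing.assert_array_equal(quantize(q.astype(float), 8), q)

    def test_constant_image_maps_to_zero(self):
        assert (quantize(np.full((4, 4), 3.3), 16) == 0).all()

    @given(arrays(np.float64, (6, 6),
                  elements=st.floats(0, 100, allow_nan=False)))
    @settings(max_examples=50, deadline=None)
    def test_monotone_pixel_ordering_preserved(self, img):
        q = quantize(img, 8)
        a, b = img.ravel(), q.ravel()
        order = np.argsort(a, kind="stable")
        assert (np.diff(b[order]) >= 0).all()


class TestGLCM:
    def test_hand_enumeration_small_image(self):
        img = np.array([[0, 0, 1, 1],
                        [0, 0, 1, 1],
                        [0, 2, 2, 2],
                        [2, 2, 3, 3]], dtype=np.int32)
        g = compute_glcm(img, (1, 0), levels=4, symmetric=False)
        # enumerate horizontally adjacent ordered pairs by hand
        expected = np.zeros((4, 4))
        for r in range(4):
            for c in range(3):
                expected[img[r, c], img[r, c + 1]] += 1
        expected /= expected.sum()
        np.testing.assert_allclose(g.p, expected)

    def test_constant_image_single_entry(self):
        g = compute_glcm(np.full((5, 5), 3, dtype=np.int32), (0, 1), levels=4)
        assert g.p[3, 3] == 1.0
        assert g.p.sum() == pytest.approx(1.0)

    def test_symmetric_matrix_is_symmetric(self, rng):
        img = rng.integers(0, 6, (12, 12)).astype(np.int32)
        g = compute_glcm(img, (2, 1), levels=6, symmetric=True)
        np.testing.assert_allclose(g.p, g.p.T)

    def test_probabilities_sum_to_one_any_offset(self, rng):
        img = rng.integers(0, 5, (10, 14)).astype(np.int32)
        for offset in [(1, 0), (0, 3), (2, 2), (-1, 4), (3, -2)]:
            g = compute_glcm(img, offset, levels=5)
            assert g.p.sum() == pytest.approx(1.0)

    def test_matches_skimage_graycomatrix(self, rng):
        from skimage.feature import graycomatrix

        img = rng.integers(0, 8, (20, 20)).astype(np.uint8)
        ours = compute_glcm(img.astype(np.int32), (1, 0), levels=8, symmetric=True)
        ref = graycomatrix(img, [1], [0], levels=8, symmetric=True, normed=True)
        np.testing.assert_allclose(ours.p, ref[:, :, 0, 0])

    def test_offset_out_of_bounds_raises(self):
        with pytest.raises(ValueError, match="offset"):
            compute_glcm(np.zeros((4, 4), dtype=np.int32), (4, 0), levels=2)


class TestGLCMCorrelation:
    def test_periodic_stripes_perfect_correlation(self):
        img = np.tile(np.array([0, 1, 2, 1], dtype=np.int32), (16, 8))
        g = compute_glcm(img, (4, 0), levels=3)
        assert glcm_correlation(g) == pytest.approx(1.0)

    def test_white_noise_near_zero(self, rng):
        img = rng.integers(0, 16, (256, 256)).astype(np.int32)
        g = compute_glcm(img, (10, 0), levels=16)
        assert abs(glcm_correlation(g)) < 0.02

    def test_constant_image_undefined(self):
        g = compute_glcm(np.zeros((8, 8), dtype=np.int32), (1, 0), levels=2)
        with pytest.raises(ValueError, match="zero marginal variance"):
            glcm_correlation(g)

    def test_equals_pairwise_pearson_on_random_images(self, rng):
        for _ in range(30):
            h, w = rng.integers(4, 17, size=2)
            G = int(rng.integers(2, 9))
            img = rng.integers(0, G, (h, w)).astype(np.int32)
            dx = int(rng.integers(-3, 4))
            dy = int(rng.integers(-3, 4))
            if (dx == 0 and dy == 0) or abs(dx) >= w or abs(dy) >= h:
                continue
            ref = pearson_over_pairs(img, (dx, dy), symmetric=True)
            if np.isnan(ref):
                continue
            got = glcm_correlation(compute_glcm(img, (dx, dy), levels=G))
            assert got == pytest.approx(ref, abs=1e-12)


class TestCorrelationCurve:
    def test_horizontal_stripes_anisotropy(self):
        img = np.tile(np.arange(64) % 2, (64, 1)).astype(float).T  # rows alternate
        curve = correlation_curve(CalibratedImage(img + 0.0), d_max=6, levels=2)
        # vertical offsets cross stripes → oscillating ±1; horizontal stay 1
        np.testing.assert_allclose(curve.horizontal, 1.0, atol=1e-12)
        assert curve.vertical[0] == pytest.approx(-1.0)
        assert curve.vertical[1] == pytest.approx(1.0)

    def test_transpose_swaps_directions_exactly(self, rng):
        img = rng.random((80, 80))
        a = correlation_curve(CalibratedImage(img), d_max=10, levels=16)
        b = correlation_curve(CalibratedImage(img.T.copy()), d_max=10, levels=16)
        np.testing.assert_allclose(a.horizontal, b.vertical)
        np.testing.assert_allclose(a.vertical, b.horizontal)

    def test_normalized_curve_starts_at_one_and_is_affine_invariant(self, rng):
        img = rng.random((64, 64))
        a = correlation_curve(CalibratedImage(img), d_max=8, levels=64).normalize()
        b = correlation_curve(CalibratedImage(3.0 * img + 10.0), d_max=8,
                              levels=64).normalize()
        assert a.horizontal[0] == 1.0 and a.vertical[0] == 1.0
        np.testing.assert_allclose(a.mean, b.mean, atol=1e-12)

    def test_too_small_image_error_reports_max_usable_d(self):
        with pytest.raises(ValueError, match="max usable d is 15"):
            correlation_curve(CalibratedImage(np.random.rand(16, 64)), d_max=100)


class TestCorrelationLengthFit:
    def test_exact_exponential_recovered(self):
        d = np.arange(1, 101)
        c = np.exp(-d / 35.0)
        curve = TextureCurve(distances=d, horizontal=c, vertical=c)
        fit = fit_correlation_length(curve)
        assert fit.corr_length_px == pytest.approx(35.0, rel=1e-3)

    def test_directions_averaged_before_fitting(self):
        d = np.arange(1, 101)
        curve = TextureCurve(distances=d,
                             horizontal=1.2 * np.exp(-d / 20.0),
                             vertical=0.8 * np.exp(-d / 20.0))
        fit = fit_correlation_length(curve)
        # mean curve is exactly exp(-d/20)
        assert fit.corr_length_px == pytest.approx(20.0, rel=1e-3)

    def test_non_decaying_curve_flagged_without_lambda(self):
        d = np.arange(1, 101)
        curve = TextureCurve(distances=d, horizontal=np.ones(100),
                             vertical=np.ones(100))
        fit = fit_correlation_length(curve)
        assert fit.non_decaying and fit.corr_length_px is None
        assert not fit.converged

    def test_fit_range_restriction(self):
        d = np.arange(1, 101)
        c = np.exp(-d / 15.0)
        curve = TextureCurve(distances=d, horizontal=c, vertical=c)
        fit = fit_correlation_length(curve, fit_range=(5, 60))
        assert fit.fit_range == (5.0, 60.0)
        assert fit.corr_length_px == pytest.approx(15.0, rel=1e-3)
        with pytest.raises(ValueError, match="at least 5 points"):
            fit_correlation_length(curve, fit_range=(5, 7))

    def test_isinstance_result(self):
        d = np.arange(1, 51)
        c = np.exp(-d / 10.0)
        fit = fit_correlation_length(TextureCurve(d, c, c))
        assert isinstance(fit, CorrelationFit)
        assert fit.corr_length_um == pytest.approx(fit.corr_length_px)


def test_thick_fibers_have_longer_correlation_length():
    """Texture of thick disordered fiber networks decays more slowly than
    thin aligned ones — the ordering behind coarser collagen textures."""
    from stromaquant.synthetic import FiberImageSpec, make_fiber_image

    thin = make_fiber_image(FiberImageSpec(image_size=512, n_fibers=60,
                                           fiber_width=2.0,
                                           orientation_concentration=8.0, seed=0))
    thick = make_fiber_image(FiberImageSpec(image_size=512, n_fibers=60,
                                            fiber_width=4.0,
                                            orientation_concentration=0.5, seed=0))
    lam_thin = estimate_correlation_length(thin, d_max=100).corr_length_px
    lam_thick = estimate_correlation_length(thick, d_max=100).corr_length_px
    assert lam_thick > lam_thin
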