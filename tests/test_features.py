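"""Texture features: hand-counted GLCMs, moment oracles, library cross-checks."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps
from skimage.feature import graycomatrix

from folliscan.features import (
    EmptyGLCMError,
    FeatureConfig,
    compute_glcm,
    extract_feature_vector,
    first_order_features,
    glcm_features,
    quantize,
)


class TestQuantize:
    def test_two_levels_threshold_at_128(self):
        assert quantize(np.array([100.0]), 2)[0] == 0
        assert quantize(np.array([200.0]), 2)[0] == 1

    def test_constant_region_single_level(self):
        lv = quantize(np.full((5, 5), 77.0), 8)
        assert len(np.unique(lv)) == 1

    @given(st.floats(0, 255), st.floats(0, 255))
    @settings(deadline=None)
    def test_monotone(self, a, b):
        la, lb = quantize(np.array([a]), 8)[0], quantize(np.array([b]), 8)[0]
        if a <= b:
            assert la <= lb

    def test_rejects_fewer_than_two_levels(self):
        with pytest.raises(ValueError):
            quantize(np.zeros(3), 1)


class TestGLCM:
    def test_constant_region_single_diagonal_entry(self):
        g = compute_glcm(np.zeros((4, 4), int), n_levels=2)
        assert g.matrix[0, 0] == pytest.approx(1.0)
        assert g.matrix.sum() == pytest.approx(1.0)

    def test_hand_counted_2x2_horizontal(self):
        """[[0,1],[0,1]] at d=1, 0 deg, symmetric: the two horizontal pairs
        (0,1) are doubled by symmetry into (0,1) = (1,0) = 0.5."""
        levels = np.array([[0, 1], [0, 1]])
        g = compute_glcm(levels, distance=1, angles=(0,), symmetric=True)
        expected = np.array([[0.0, 0.5], [0.5, 0.0]])
        assert np.allclose(g.matrix, expected)

    def test_hand_counted_features_of_2x2_case(self):
        levels = np.array([[0, 1], [0, 1]])
        g = compute_glcm(levels, distance=1, angles=(0,), symmetric=True)
        f = glcm_features(g)
        assert f["contrast"] == pytest.approx(1.0)
        assert f["homogeneity"] == pytest.approx(0.5)
        assert f["energy"] == pytest.approx(0.5)
        assert f["entropy"] == pytest.approx(np.log(2))
        assert f["correlation"] == pytest.approx(-1.0)  # levels perfectly alternate

    def test_constant_region_feature_limits(self):
        g = compute_glcm(np.zeros((4, 4), int), n_levels=2)
        f = glcm_features(g)
        assert f["contrast"] == 0.0
        assert f["energy"] == pytest.approx(1.0)
        assert f["homogeneity"] == pytest.approx(1.0)
        assert f["entropy"] == pytest.approx(0.0)

    def test_diagonal_glcm_has_unit_correlation(self):
        from folliscan.features import GLCM

        ng = 4
        g = GLCM(
            matrix=np.eye(ng) / ng, n_levels=ng, distance=1,
            angles=(0,), symmetric=True, normalized=True,
        )
        assert glcm_features(g)["correlation"] == pytest.approx(1.0, abs=1e-9)

    def test_pairs_require_both_pixels_in_mask(self):
        levels = np.array([[0, 1, 0], [1, 0, 1]])
        mask = np.array([[True, True, False], [False, False, False]])
        # only the single pair (0,1) in the top row survives the mask
        g = compute_glcm(levels, mask, angles=(0,), symmetric=False, n_levels=2)
        assert g.matrix[0, 1] == pytest.approx(1.0)
        assert g.matrix.sum() == pytest.approx(1.0)

    def test_empty_mask_raises(self):
        levels = np.zeros((3, 3), int)
        mask = np.zeros((3, 3), bool)
        mask[0, 0] = True  # a single pixel has no co-occurring neighbour
        with pytest.raises(EmptyGLCMError):
            compute_glcm(levels, mask, angles=(0,))

    def test_matches_skimage_on_unmasked_rectangles(self, rng):
        """Independent cross-check: on a full rectangle the masked GLCM must
        agree with skimage's graycomatrix accumulated over the same angles."""
        levels = rng.integers(0, 8, size=(20, 30))
        ours = compute_glcm(levels, distance=1, angles=(0, 45, 90, 135), symmetric=True)
        ref = graycomatrix(
            levels.astype(np.uint8),
            distances=[1],
            angles=[0, np.pi / 4, np.pi / 2, 3 * np.pi / 4],
            levels=8,
            symmetric=True,
            normed=False,
        )[:, :, 0, :].sum(axis=2)
        assert np.allclose(ours.matrix, ref / ref.sum())

    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=25)
    def test_normalized_glcm_sums_to_one_and_energy_in_unit_interval(self, seed):
        lv = np.random.default_rng(seed).integers(0, 6, size=(8, 8))
        g = compute_glcm(lv, n_levels=6)
        assert g.matrix.sum() == pytest.approx(1.0, abs=1e-9)
        f = glcm_features(g)
        assert 0 < f["energy"] <= 1.0
        # contrast vanishes iff all mass is diagonal
        assert (f["contrast"] == 0) == np.allclose(g.matrix, np.diag(np.diag(g.matrix)))


class TestFirstOrder:
    def test_constant_region_degenerate_convention(self):
        f = first_order_features(np.full(10, 7.0))
        assert f == {
            "mean": 7.0, "variance": 0.0, "std_dev": 0.0, "skewness": 0.0, "kurtosis": 0.0,
        }

    def test_symmetric_two_point_closed_form(self):
        f = first_order_features(np.array([0.0, 1.0] * 50))
        assert f["mean"] == pytest.approx(0.5)
        assert f["variance"] == pytest.approx(0.25)
        assert f["skewness"] == pytest.approx(0.0, abs=1e-12)
        assert f["kurtosis"] == pytest.approx(1.0)

    def test_standard_normal_moments(self):
        x = np.random.default_rng(7).standard_normal(100_000)
        f = first_order_features(x)
        assert abs(f["skewness"]) < 0.05
        assert f["kurtosis"] == pytest.approx(3.0, abs=0.1)

    def test_agrees_with_scipy_population_moments(self, rng):
        x = rng.gamma(2.0, 3.0, size=1000)
        f = first_order_features(x)
        assert f["skewness"] == pytest.approx(sps.skew(x, bias=True), abs=1e-12)
        assert f["kurtosis"] == pytest.approx(
            sps.kurtosis(x, fisher=False, bias=True), abs=1e-12
        )

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            first_order_features(np.array([]))


class TestFeatureVector:
    def test_constant_masked_region_assembles_limit_values(self):
        img = np.full((10, 10), 42.0)
        mask = np.zeros((10, 10), bool)
        mask[2:8, 2:8] = True
        fv = extract_feature_vector(img, mask)
        assert fv.mean == 42.0
        assert fv.variance == fv.std_dev == 0.0
        assert fv.energy == pytest.approx(1.0)
        assert fv.homogeneity == pytest.approx(1.0)
        assert fv.contrast == fv.entropy == 0.0
        assert fv.skewness == fv.kurtosis == 0.0

    def test_deterministic_row(self, pcos_phantom, preprocessed_pcos):
        a = extract_feature_vector(preprocessed_pcos, pcos_phantom.mask)
        b = extract_feature_vector(preprocessed_pcos, pcos_phantom.mask)
        assert a.to_dict() == b.to_dict()

    def test_empty_mask_without_fallback_raises(self):
        img = np.full((8, 8), 10.0)
        with pytest.raises(ValueError):
            extract_feature_vector(
                img, np.zeros((8, 8), bool), FeatureConfig(whole_image_fallback=False)
            )

    def test_variance_is_square_of_std(self, pcos_phantom, preprocessed_pcos):
        fv = extract_feature_vector(preprocessed_pcos, pcos_phantom.mask)
        assert fv.variance == pytest.approx(fv.std_dev**2)
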