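"""Texture descriptors vs hand computations and brute-force enumeration oracles."""

import numpy as np
import pytest
import pywt
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from oracles import brute_glcm, brute_glcm_features, brute_glrlm, brute_glrlm_features

from iristex.errors import ConfigError, EmptyGLRLMError
from iristex.features import (
    BAND_ORDER,
    DIRECTIONS_DEG,
    directional_average,
    dwt2_level1,
    extract_feature_vector,
    feature_names,
    first_order_stats,
    glcm,
    glcm_features,
    glrlm,
    glrlm_features,
    quantize,
)

CHECKER = (np.indices((4, 4)).sum(axis=0) % 2).astype(np.int64)


class TestWavelet:
    def test_constant_input_zero_details(self):
        sb = dwt2_level1(np.full((8, 8), 13.0))
        assert np.allclose(sb.cH, 0) and np.allclose(sb.cV, 0) and np.allclose(sb.cD, 0)
        assert np.ptp(sb.cA) == pytest.approx(0.0)

    def test_roi_halves_to_95_by_60(self, rng):
        sb = dwt2_level1(rng.uniform(0, 255, (190, 120)))
        for band in (sb.cA, sb.cH, sb.cV, sb.cD):
            assert band.shape == (95, 60)

    def test_perfect_reconstruction_and_energy(self, rng):
        roi = rng.uniform(0, 255, (190, 120))
        sb = dwt2_level1(roi)
        rec = pywt.idwt2((sb.cA, (sb.cH, sb.cV, sb.cD)), "haar", mode="periodization")
        assert np.abs(rec - roi).max() < 1e-9
        e_in = (roi**2).sum()
        e_out = sum((b**2).sum() for b in (sb.cA, sb.cH, sb.cV, sb.cD))
        assert abs(e_in - e_out) / e_in < 1e-6

    def test_unknown_wavelet(self):
        with pytest.raises(ConfigError):
            dwt2_level1(np.zeros((8, 8)), "not-a-wavelet")


class TestFirstOrderStats:
    def test_constant(self):
        assert first_order_stats(np.full((5, 5), 3.0)) == (3.0, 0.0, 0.0, 0.0, 0.0)

    def test_balanced_binary_entropy_one_bit(self):
        band = np.array([[0.0, 1.0], [1.0, 0.0]])
        _, _, entropy, _, _ = first_order_stats(band)
        assert entropy == pytest.approx(1.0)

    def test_small_sample_moments(self):
        mean, std, _, skew, kurt = first_order_stats(np.array([1.0, 2.0, 3.0, 4.0]))
        assert mean == pytest.approx(2.5)
        assert std == pytest.approx(np.sqrt(5.0 / 3.0), abs=1e-9)  # 1.29099...
        assert skew == pytest.approx(0.0, abs=1e-12)
        # m4/m2^2 for the symmetric 4-point set: m2=1.25, m4=2.5625
        assert kurt == pytest.approx(2.5625 / 1.25**2)


class TestQuantize:
    def test_full_range_8bit_bins(self):
        band = np.arange(256, dtype=float)
        q = quantize(band, 8)
        assert np.array_equal(q, np.minimum(band * 8 // 256, 7))

    def test_constant_maps_to_zero(self):
        assert np.array_equal(quantize(np.full((3, 3), 4.2), 16), np.zeros((3, 3)))

    def test_signed_coefficients_in_range(self, rng):
        q = quantize(rng.normal(0, 30, (20, 20)), 16)
        assert q.min() == 0 and q.max() == 15


class TestGlcm:
    def test_two_by_two_hand_enumeration(self):
        P = glcm(np.array([[0, 0], [1, 1]]), 2, 0)
        assert P[0, 0] == pytest.approx(0.5)
        assert P[1, 1] == pytest.approx(0.5)
        assert P[0, 1] == P[1, 0] == 0.0

    def test_normalization(self, rng):
        P = glcm(rng.integers(0, 8, (9, 7)), 8, 45)
        assert P.sum() == pytest.approx(1.0)
        assert np.allclose(P, P.T)  # symmetric accumulation

    def test_constant_image_single_entry(self):
        P = glcm(np.zeros((4, 4), int), 8, 90)
        assert P[0, 0] == pytest.approx(1.0)
        feats = glcm_features(P)
        # energy 1, entropy 0, contrast 0, homogeneity 1, max prob 1
        assert feats[8] == pytest.approx(1.0)
        assert feats[9] == pytest.approx(0.0)
        assert feats[3] == pytest.approx(0.0)
        assert feats[10] == pytest.approx(1.0)
        assert feats[14] == pytest.approx(1.0)

    def test_checkerboard_hand_values(self):
        feats = glcm_features(glcm(CHECKER, 2, 0))
        assert feats[3] == pytest.approx(1.0)  # contrast
        assert feats[7] == pytest.approx(1.0)  # dissimilarity
        assert feats[8] == pytest.approx(0.5)  # energy

    def test_feature_vector_length(self, rng):
        feats = glcm_features(glcm(rng.integers(0, 8, (12, 12)), 8, 135))
        assert feats.shape == (22,)

    @pytest.mark.parametrize("theta", DIRECTIONS_DEG)
    def test_matrix_matches_brute_force(self, toys, theta):
        for name, mat in toys.items():
            if theta != 0 and mat.shape[0] < 2:
                continue  # single-row fixture has no vertical/diagonal pairs
            levels = int(mat.max()) + 1 if mat.max() > 0 else 2
            got = glcm(mat, levels, theta)
            want = brute_glcm(mat, levels, theta)
            np.testing.assert_allclose(got, want, atol=1e-12)

    @pytest.mark.parametrize("theta", DIRECTIONS_DEG)
    def test_features_match_brute_force(self, toys, theta):
        for name, mat in toys.items():
            if theta != 0 and mat.shape[0] < 2:
                continue
            levels = int(mat.max()) + 1 if mat.max() > 0 else 2
            P = glcm(mat, levels, theta)
            np.testing.assert_allclose(
                glcm_features(P), brute_glcm_features(P), atol=1e-12
            )

    def test_image_smaller_than_offset_raises(self):
        from iristex.errors import EmptyGLCMError

        with pytest.raises(EmptyGLCMError):
            glcm(np.array([[0, 0, 1, 1, 0]]), 2, 90)

    def test_rotation_maps_0_to_90(self, rng):
        q = rng.integers(0, 8, (10, 13))
        a = glcm_features(glcm(q, 8, 0))
        b = glcm_features(glcm(np.rot90(q), 8, 90))
        np.testing.assert_allclose(a, b, atol=1e-12)


class TestGlrlm:
    def test_single_row_runs(self):
        R = glrlm(np.array([[0, 0, 0, 1, 1]]), 2, 0)
        assert R[0, 2] == 1 and R[1, 1] == 1
        assert R.sum() == 2

    def test_single_row_features_hand_values(self):
        R = glrlm(np.array([[0, 0, 0, 1, 1]]), 2, 0)
        sre, lre, gln, rp, rln, lgre, hgre = glrlm_features(R, 5)
        assert sre == pytest.approx((1 / 9 + 1 / 4) / 2)  # 0.18055...
        assert lre == pytest.approx(6.5)
        assert rp == pytest.approx(2 / 5)

    def test_constant_five_by_five(self):
        R = glrlm(np.zeros((5, 5), int), 2, 0)
        feats = glrlm_features(R, 25)
        assert feats[1] == pytest.approx(25.0)  # LRE: 5 runs of length 5
        assert feats[3] == pytest.approx(5 / 25)  # RP

    def test_checkerboard_all_unit_runs(self):
        R = glrlm(CHECKER, 2, 0)
        sre, lre, _, rp, _, _, _ = glrlm_features(R, CHECKER.size)
        assert sre == pytest.approx(1.0) and lre == pytest.approx(1.0)
        assert rp == pytest.approx(1.0)

    @pytest.mark.parametrize("theta", DIRECTIONS_DEG)
    def test_matches_brute_force(self, toys, theta):
        for name, mat in toys.items():
            levels = int(mat.max()) + 1 if mat.max() > 0 else 2
            got = glrlm(mat, levels, theta)
            want = brute_glrlm(mat, levels, theta)
            np.testing.assert_allclose(got, want, atol=0)
            np.testing.assert_allclose(
                glrlm_features(got, mat.size),
                brute_glrlm_features(want, mat.size),
                atol=1e-12,
            )

    @settings(max_examples=25, deadline=None)
    @given(
        arrays(np.int64, st.tuples(st.integers(2, 8), st.integers(2, 8)),
               elements=st.integers(0, 3)),
        st.sampled_from(DIRECTIONS_DEG),
    )
    def test_runs_partition_pixels(self, mat, theta):
        R = glrlm(mat, 4, theta)
        j = np.arange(1, R.shape[1] + 1)
        assert (R * j[None, :]).sum() == mat.size

    def test_empty_matrix_raises(self):
        with pytest.raises(EmptyGLRLMError):
            glrlm_features(np.zeros((4, 4)), 0)


class TestAssembly:
    def test_directional_average(self):
        four = [np.array([1.0, 2.0]), np.array([3.0, 4.0]),
                np.array([5.0, 6.0]), np.array([7.0, 8.0])]
        np.testing.assert_allclose(directional_average(four), [4.0, 5.0])
        with pytest.raises(ValueError):
            directional_average(four[:3])
        same = {t: np.array([2.5]) for t in DIRECTIONS_DEG}
        np.testing.assert_allclose(directional_average(same), [2.5])

    def test_isotropic_texture_near_equal_contrast(self, rng):
        from scipy.ndimage import gaussian_filter

        tex = gaussian_filter(rng.standard_normal((128, 128)), 2.0)
        q = quantize(tex, 8)
        contrasts = [glcm_features(glcm(q, 8, t))[3] for t in DIRECTIONS_DEG]
        # diagonal offsets span sqrt(2) distance; compare like with like
        assert abs(contrasts[0] - contrasts[2]) / contrasts[0] < 0.1
        assert abs(contrasts[1] - contrasts[3]) / contrasts[1] < 0.1

    def test_vector_is_136_with_34_per_band(self, rng):
        fv = extract_feature_vector(rng.uniform(0, 255, (190, 120)))
        assert len(fv) == 136
        assert len(fv.names) == 136
        for bi, band in enumerate(BAND_ORDER):
            chunk = fv.names[34 * bi : 34 * (bi + 1)]
            assert all(n.startswith(band + "_") for n in chunk)

    def test_extraction_deterministic(self, rng):
        roi = rng.uniform(0, 255, (64, 64))
        a = extract_feature_vector(roi)
        b = extract_feature_vector(roi)
        assert np.array_equal(a.values, b.values)
        assert a.names == b.names == feature_names()
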