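"""Matrix-family features against brute-force enumeration oracles."""

import numpy as np
import pytest

from mammoread.prep import quantize
from mammoread.radiomics import (GLCMConfig, fractal_dimension, glcm_features,
                                 glcm_features_from_matrix, glcm_matrix,
                                 glds_features, glrlm_features, glsm_features,
                                 ngtdm_features, run_length_matrix,
                                 sfm_features)

from .conftest import random_quantized
from .oracles import (glcm_counts_bruteforce, glcm_features_bruteforce,
                      glds_features_bruteforce, glrlm_features_bruteforce,
                      ngtdm_features_bruteforce, sfm_features_bruteforce)


class TestGLCM:
    def test_two_by_two_horizontal_pairs(self):
        img = np.array([[0, 0], [1, 1]])
        P = glcm_matrix(img, 1, angles_deg=(0,))
        # two horizontal pairs, symmetric: P(0,0)=P(1,1)=1/2
        assert P[0, 0] == pytest.approx(0.5)
        assert P[1, 1] == pytest.approx(0.5)
        feats = glcm_features_from_matrix(P)
        assert feats["energy"] == pytest.approx(0.5)
        assert feats["contrast"] == pytest.approx(0.0)

    def test_constant_image_degenerates(self):
        flags = []
        feats = glcm_features_from_matrix(
            glcm_matrix(np.zeros((4, 4), dtype=int), 1), flags, "_d1")
        assert feats["contrast"] == 0.0
        assert feats["energy"] == pytest.approx(1.0)
        assert feats["correlation"] == 0.0
        assert any("correlation" in f for f in flags)

    def test_checkerboard_contrast_matches_enumeration(self):
        img = np.indices((6, 6)).sum(axis=0) % 2
        P = glcm_matrix(img, 1)
        oracle = glcm_counts_bruteforce(img, 1, levels=2)
        assert np.allclose(P, oracle / oracle.sum())
        feats = glcm_features_from_matrix(P)
        expect = glcm_features_bruteforce(oracle)
        assert feats["contrast"] == pytest.approx(expect["contrast"])

    def test_counts_match_bruteforce_on_random_images(self, rng):
        for _ in range(25):
            img = random_quantized(rng)
            for d in (1, 3, 5):
                counts = glcm_counts_bruteforce(img, d, levels=4)
                ours = glcm_matrix(
                    type("Q", (), {"array": img, "levels": 4})(), d)
                if counts.sum() > 0:
                    assert np.allclose(ours, counts / counts.sum())

    def test_all_22_features_match_bruteforce(self, rng):
        for _ in range(20):
            img = random_quantized(rng)
            P = glcm_matrix(type("Q", (), {"array": img, "levels": 4})(), 1)
            ours = glcm_features_from_matrix(P)
            oracle = glcm_features_bruteforce(
                glcm_counts_bruteforce(img, 1, levels=4))
            for name, v in oracle.items():
                assert ours[name] == pytest.approx(v, abs=1e-9), name

    def test_offset_larger_than_roi_yields_flagged_zeros(self):
        flags = []
        img = random_quantized(np.random.default_rng(0))
        out = glcm_features(type("Q", (), {"array": img, "levels": 4})(),
                            GLCMConfig(), flags)
        assert len(out) == 88
        assert all(out[f"glcm_d9_{n}"] == 0.0
                   for n in GLCMConfig().feature_names)
        assert any("offset 9" in f for f in flags)


class TestGLRLM:
    def test_single_row_run_percentage(self):
        img = np.array([[0, 0, 0, 1]])
        R = run_length_matrix(img, 2, 0)
        # runs: (level 0, length 3) and (level 1, length 1)
        assert R[0, 2] == 1 and R[1, 0] == 1
        assert R.sum() == 2  # run percentage = 2/4 along 0 deg

    def test_constant_row_long_run_emphasis(self):
        n = 7
        img = np.full((1, n), 2)
        R = run_length_matrix(img, 3, 0)
        n_runs = R.sum()
        j = np.arange(1, R.shape[1] + 1)
        lre = (R.sum(axis=0) * j ** 2).sum() / n_runs
        assert n_runs == 1 and lre == n ** 2

    def test_six_features_match_bruteforce(self, rng):
        for _ in range(20):
            img = random_quantized(rng)
            ours = glrlm_features(type("Q", (), {"array": img,
                                                 "levels": 4})())
            oracle = glrlm_features_bruteforce(img, 4)
            for name, v in oracle.items():
                assert ours[f"glrlm_{name}"] == pytest.approx(v, abs=1e-9), \
                    name


class TestGLSM:
    def test_constant_roi_flat_gradient(self):
        out = glsm_features(np.full((6, 6), 4.0))
        assert out["glsm_mean"] == 0.0
        assert out["glsm_variance"] == 0.0
        assert out["glsm_entropy"] == 0.0

    def test_linear_ramp_gradient_magnitude(self):
        yy, xx = np.mgrid[0:10, 0:10].astype(float)
        s = 1.7
        out = glsm_features(s * xx)
        assert out["glsm_mean"] == pytest.approx(s)
        assert out["glsm_variance"] == pytest.approx(0.0, abs=1e-12)

    def test_too_small_roi_rejected(self):
        with pytest.raises(ValueError):
            glsm_features(np.zeros((2, 5)))


class TestGLDS:
    def test_constant_roi(self):
        out = glds_features(np.full((9, 9), 1.0))
        for w in (3, 5, 7):
            assert out[f"glds_w{w}_mean"] == 0.0
            assert out[f"glds_w{w}_energy"] == 1.0
            assert out[f"glds_w{w}_entropy"] == 0.0

    def test_matches_direct_windowed_computation(self, rng):
        for _ in range(10):
            roi = rng.normal(size=(9, 9))
            ours = glds_features(roi)
            for w in (3, 5, 7):
                oracle = glds_features_bruteforce(roi, w)
                for stat, v in oracle.items():
                    assert ours[f"glds_w{w}_{stat}"] == \
                        pytest.approx(v, abs=1e-9), (w, stat)

    def test_single_bright_pixel_produces_local_response(self):
        roi = np.zeros((15, 15))
        roi[7, 7] = 10.0
        out = glds_features(roi)
        for w in (3, 5, 7):
            assert out[f"glds_w{w}_mean"] > 0
            assert out[f"glds_w{w}_contrast"] > 0

    def test_small_roi_flags_affected_windows(self):
        flags = []
        out = glds_features(np.random.default_rng(0).normal(size=(4, 4)),
                            flags)
        assert out["glds_w5_mean"] == 0.0 and out["glds_w7_mean"] == 0.0
        assert out["glds_w3_mean"] > 0.0
        assert len([f for f in flags if "glds" in f]) == 2


class TestNGTDM:
    def test_constant_image(self):
        q = type("Q", (), {"array": np.zeros((8, 8), dtype=int),
                           "levels": 4})()
        out = ngtdm_features(q)
        assert out["ngtdm_r1_coarseness"] == 1e6  # capped reciprocal
        assert out["ngtdm_r1_contrast"] == 0.0

    def test_worked_4x4_example_matches_hand_enumeration(self):
        img = np.array([[0, 1, 2, 3],
                        [1, 1, 0, 2],
                        [3, 0, 1, 1],
                        [2, 2, 0, 3]])
        q = type("Q", (), {"array": img, "levels": 4})()
        ours = ngtdm_features(q)
        oracle = ngtdm_features_bruteforce(img, 4, 1)
        for name, v in oracle.items():
            assert ours[f"ngtdm_r1_{name}"] == pytest.approx(v, abs=1e-9), \
                name

    def test_all_radii_match_bruteforce_on_random_images(self, rng):
        for _ in range(10):
            img = random_quantized(rng, size=8)
            q = type("Q", (), {"array": img, "levels": 4})()
            ours = ngtdm_features(q)
            for r in (1, 2, 3):
                oracle = ngtdm_features_bruteforce(img, 4, r)
                for name, v in oracle.items():
                    assert ours[f"ngtdm_r{r}_{name}"] == \
                        pytest.approx(v, abs=1e-9), (r, name)


class TestSFM:
    def test_constant_image_zero_contrast(self):
        q = type("Q", (), {"array": np.full((12, 12), 3, dtype=int),
                           "levels": 4})()
        out = sfm_features(q)
        assert out["sfm_l4_contrast"] == 0.0
        assert out["sfm_l8_contrast"] == 0.0

    def test_matches_bruteforce_construction(self, rng):
        for _ in range(5):
            img = random_quantized(rng, size=10)
            q = type("Q", (), {"array": img, "levels": 4})()
            ours = sfm_features(q)
            oracle = sfm_features_bruteforce(img, 4)
            for name, v in oracle.items():
                assert ours[f"sfm_l4_{name}"] == pytest.approx(v, abs=1e-9), \
                    name

    def test_periodicity_peaks_at_matching_spacing(self):
        # a texture periodic with period 8 along both axes: only the
        # spacing-8 displacement set contains a zero-dissimilarity lag
        yy, xx = np.mgrid[0:24, 0:24].astype(float)
        img = np.round(2 * np.cos(2 * np.pi * xx / 8)
                       + 2 * np.cos(2 * np.pi * yy / 8)).astype(int) + 4
        q = type("Q", (), {"array": img, "levels": int(img.max()) + 1})()
        out = sfm_features(q)
        assert out["sfm_l8_periodicity"] > out["sfm_l4_periodicity"]
        assert out["sfm_l8_periodicity"] > 0.9


class TestFractal:
    def test_flat_plane_dimension_near_two(self):
        yy, xx = np.mgrid[0:64, 0:64].astype(float)
        out = fractal_dimension(0.3 * xx + 0.7 * yy)
        assert out["fractal_dimension"] == pytest.approx(2.0, abs=0.1)

    def test_white_noise_rougher_than_plane(self, rng):
        noise = rng.normal(size=(64, 64))
        yy, xx = np.mgrid[0:64, 0:64].astype(float)
        d_noise = fractal_dimension(noise)["fractal_dimension"]
        d_plane = fractal_dimension(xx + yy)["fractal_dimension"]
        assert d_noise > d_plane
        assert d_noise < 3.2

    def test_small_roi_uses_fewer_scales_with_flag(self):
        flags = []
        out = fractal_dimension(np.random.default_rng(1).normal(size=(16, 16)),
                                flags)
        assert np.isfinite(out["fractal_dimension"])
        assert any("scales" in f for f in flags)

    def test_constant_roi_flagged(self):
        flags = []
        out = fractal_dimension(np.ones((32, 32)), flags)
        assert out["fractal_dimension"] == 2.0
        assert flags
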