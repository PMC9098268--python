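"""Unit tests for the non-matrix feature groups: histogram, AR model,
gradient, HOG, Gabor, wavelet energies, quantization, and the assembled
250-feature vector."""

import math

import numpy as np
import pytest

from echotexture import (
    FEATURE_NAMES,
    GROUPS,
    ar_model_features,
    extract_all,
    gabor_features,
    gradient_features,
    histogram_features,
    hog_features,
    quantize,
    wavelet_energy_features,
)
from echotexture.registry import GABOR_SIZES

from conftest import random_float_image


# ------------------------------------------------------------------ histogram

class TestHistogram:
    def test_constant_image(self):
        f = histogram_features(np.full((8, 8), 7.0))
        assert f["Mean"] == 7 and f["Variance"] == 0
        assert f["Perc50"] == 7 and f["Skewness"] == 0 and f["Kurtosis"] == 0

    def test_two_value_image_population_moments(self):
        f = histogram_features(np.array([[0.0, 0.0], [255.0, 255.0]]))
        assert f["Mean"] == pytest.approx(127.5)
        assert f["Variance"] == pytest.approx(16256.25)
        assert f["Skewness"] == pytest.approx(0.0)

    def test_nearest_rank_percentiles_on_ramp(self):
        f = histogram_features(np.arange(1, 101, dtype=float).reshape(1, 100))
        assert f["Perc01"] == 1 and f["Perc10"] == 10 and f["Perc99"] == 99

    def test_intensity_scaling(self):
        img = random_float_image(0, (16, 16))
        f1, f2 = histogram_features(img), histogram_features(3.0 * img)
        assert f2["Mean"] == pytest.approx(3 * f1["Mean"])
        assert f2["Perc90"] == pytest.approx(3 * f1["Perc90"])
        assert f2["Variance"] == pytest.approx(9 * f1["Variance"])
        assert f2["Skewness"] == pytest.approx(f1["Skewness"])


# ------------------------------------------------------------------ AR model

class TestARModel:
    def test_constant_image_degenerate_convention(self):
        f = ar_model_features(np.full((8, 8), 3.0))
        assert all(v == 0.0 for v in f.values())

    def test_parameter_recovery_on_simulated_field(self):
        theta = (0.4, 0.1, 0.3, 0.1)
        rng = np.random.default_rng(7)
        n = 256
        z = np.zeros((n, n))
        noise = rng.standard_normal((n, n))
        for y in range(1, n):
            for x in range(1, n - 1):
                z[y, x] = (
                    theta[0] * z[y, x - 1]
                    + theta[1] * z[y - 1, x - 1]
                    + theta[2] * z[y - 1, x]
                    + theta[3] * z[y - 1, x + 1]
                    + noise[y, x]
                )
        f = ar_model_features(z)
        for est, true in zip([f["Teta1"], f["Teta2"], f["Teta3"], f["Teta4"]], theta):
            assert abs(est - true) < 0.05

    def test_white_noise_sigma_matches_image_sd(self):
        img = np.random.default_rng(3).standard_normal((128, 128))
        f = ar_model_features(img)
        assert 0.95 < f["Sigma"] / img.std() < 1.05


# ------------------------------------------------------------------ gradient

class TestGradient:
    def test_constant_image_all_zero(self):
        f = gradient_features(np.full((8, 8), 5.0))
        assert all(v == 0.0 for v in f.values())

    def test_vertical_step_edge_nonzeros(self):
        img = np.zeros((6, 6))
        img[:, 3:] = 100.0
        f = gradient_features(img)
        assert f["GrNonZeros"] == pytest.approx(50.0)

    def test_rotation_invariance(self):
        img = random_float_image(5, (16, 16))
        f1 = gradient_features(img)
        f2 = gradient_features(np.rot90(img))
        for k in f1:
            assert f1[k] == pytest.approx(f2[k], rel=1e-10)

    def test_offset_invariance(self):
        img = random_float_image(6, (16, 16))
        f1 = gradient_features(img)
        f2 = gradient_features(img + 37.0)
        for k in f1:
            assert f1[k] == pytest.approx(f2[k], rel=1e-9)


# ------------------------------------------------------------------ HOG

class TestHOG:
    def test_constant_image_no_votes(self):
        f = hog_features(np.full((8, 8), 9.0))
        assert all(v == 0.0 for v in f.values())

    def test_horizontal_ramp_votes_at_zero_degrees(self):
        img = np.tile(np.arange(16, dtype=float), (16, 1))
        f = hog_features(img)
        for b in (4, 8, 16):
            assert f[f"O{b}b0"] == pytest.approx(1.0)

    def test_histograms_sum_to_one(self):
        f = hog_features(random_float_image(2, (16, 16)))
        for b in (4, 8, 16):
            assert sum(f[f"O{b}b{i}"] for i in range(b)) == pytest.approx(1.0)


# ------------------------------------------------------------------ Gabor

class TestGabor:
    def test_rotation_swaps_orientations(self):
        img = random_float_image(4, (160, 160))
        f1 = gabor_features(img)
        f2 = gabor_features(np.rot90(img))
        for s in GABOR_SIZES:
            assert f1[f"Gab{s}H"] == pytest.approx(f2[f"Gab{s}V"], rel=1e-9)
            assert f1[f"Gab{s}V"] == pytest.approx(f2[f"Gab{s}H"], rel=1e-9)
            assert f1[f"Gab{s}Z"] == pytest.approx(f2[f"Gab{s}N"], rel=1e-9)
            assert f1[f"Gab{s}N"] == pytest.approx(f2[f"Gab{s}Z"], rel=1e-9)

    def test_matched_sinusoid_maximizes_gab8v(self):
        y = np.arange(256, dtype=float)[:, None]
        img = 100.0 + 50.0 * np.cos(2 * np.pi * y / 16.0) * np.ones((1, 256))
        f = gabor_features(img)
        assert max(f, key=f.get) == "Gab8V"

    def test_constant_image_near_zero(self):
        f = gabor_features(np.full((128, 128), 200.0))
        assert all(abs(v) < 1e-6 * 255 for v in f.values())

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError, match="Gabor support"):
            gabor_features(np.zeros((64, 64)))


# ------------------------------------------------------------------ wavelet

class TestWaveletEnergy:
    def test_constant_image_zero_energies(self):
        f = wavelet_energy_features(np.full((256, 256), 13.0))
        assert all(v == 0.0 for v in f.values())

    def test_pixel_checkerboard_energy_in_level1_hh(self):
        i, j = np.mgrid[0:256, 0:256]
        img = np.where((i + j) % 2 == 0, 1.0, -1.0)
        f = wavelet_energy_features(img)
        assert f["HaarS1HH"] > 0
        assert f["HaarS1LH"] == pytest.approx(0.0, abs=1e-12)
        assert f["HaarS1HL"] == pytest.approx(0.0, abs=1e-12)
        for k in range(2, 9):
            for c in ("LH", "HL", "HH"):
                assert f[f"HaarS{k}{c}"] == pytest.approx(0.0, abs=1e-12)

    def test_block_checkerboard_energy_in_level2(self):
        i, j = np.mgrid[0:256, 0:256]
        img = np.where(((i // 2) + (j // 2)) % 2 == 0, 1.0, -1.0)
        f = wavelet_energy_features(img)
        assert f["HaarS2HH"] > 0
        for k in (1, 3, 4, 5, 6, 7, 8):
            assert f[f"HaarS{k}HH"] == pytest.approx(0.0, abs=1e-12)

    def test_offset_invariance(self):
        img = random_float_image(9, (64, 64))
        f1 = wavelet_energy_features(img)
        f2 = wavelet_energy_features(img + 100.0)
        for k in f1:
            assert f1[k] == pytest.approx(f2[k], rel=1e-9, abs=1e-12)

    def test_small_image_fills_and_flags(self):
        with pytest.warns(RuntimeWarning, match="Haar levels"):
            f = wavelet_energy_features(random_float_image(1, (64, 64)))
        assert f["HaarS7HH"] == 0.0 and f["HaarS8HH"] == 0.0


# ------------------------------------------------------------------ quantize

class TestQuantize:
    def test_constant_image_single_level(self):
        q = quantize(np.full((8, 8), 42.0), levels=64, method="full_range")
        assert set(np.unique(q.pixels)) == {0}

    def test_ramp_full_range_64_levels(self):
        q = quantize(np.arange(256, dtype=float).reshape(16, 16),
                     levels=64, method="full_range")
        vals, counts = np.unique(q.pixels, return_counts=True)
        assert len(vals) == 64 and np.all(counts == 4)

    def test_mu3sigma_clips_gaussian_tails(self):
        img = np.random.default_rng(0).normal(128, 10, (200, 200))
        q = quantize(img, levels=64, method="mu_3sigma")
        clipped = np.mean(
            (img < q.mu - 3 * q.sigma) | (img > q.mu + 3 * q.sigma)
        )
        assert clipped < 0.003  # Gaussian tail mass beyond 3 sigma ~ 0.27%

    def test_invalid_levels_rejected(self):
        with pytest.raises(ValueError, match="levels"):
            quantize(np.zeros((4, 4)), levels=10)


# ------------------------------------------------------------------ battery

class TestExtractAll:
    def test_vector_length_group_sizes_and_names(self):
        img = np.random.default_rng(0).integers(0, 256, (256, 256))
        vec = extract_all(img)
        assert len(vec) == 250
        assert tuple(vec) == FEATURE_NAMES
        sizes = [len(v) for v in GROUPS.values()]
        assert sizes == [9, 5, 5, 28, 24, 24, 28, 11, 116]
        assert all(math.isfinite(v) for v in vec.values())

    def test_extraction_is_deterministic(self):
        img = np.random.default_rng(1).integers(0, 256, (128, 128))
        v1, v2 = extract_all(img), extract_all(img)
        assert list(v1.values()) == list(v2.values())
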