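"""Gaussian fitting, adaptive thresholding, segmentation and features."""

import numpy as np
import pytest

from radr.detect import DetectParams, FocusCandidate, find_candidates
from radr.segment import (adaptive_threshold, extract_features, fit_gaussian,
                          segment_focus)


def gaussian_image(shape, A, x0, y0, sigma, b):
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return b + A * np.exp(-((cc - x0) ** 2 + (rr - y0) ** 2) / (2 * sigma**2))


def candidate_at(r, c, area=9):
    rows, cols = np.mgrid[r - 1 : r + 2, c - 1 : c + 2]
    return FocusCandidate(id=0, seed=(r, c), rows=rows.ravel(), cols=cols.ravel())


class TestFitGaussian:
    def test_exact_noiseless_recovery(self):
        img = gaussian_image((41, 41), A=100.0, x0=20.0, y0=20.0, sigma=2.0, b=10.0)
        fit = fit_gaussian(img, candidate_at(20, 20))
        assert fit.converged
        assert fit.A == pytest.approx(100.0, rel=1e-4)
        assert fit.sigma == pytest.approx(2.0, rel=1e-4)
        assert fit.b == pytest.approx(10.0, abs=1e-2)
        assert fit.x0 == pytest.approx(20.0, abs=1e-4)
        assert fit.y0 == pytest.approx(20.0, abs=1e-4)

    def test_subpixel_center_recovery(self):
        img = gaussian_image((41, 41), A=80.0, x0=20.4, y0=19.7, sigma=2.5, b=50.0)
        fit = fit_gaussian(img, candidate_at(20, 20))
        assert fit.x0 == pytest.approx(20.4, abs=1e-3)
        assert fit.y0 == pytest.approx(19.7, abs=1e-3)

    def test_constant_window_degenerate(self):
        img = np.full((41, 41), 55.0)
        fit = fit_gaussian(img, candidate_at(20, 20))
        assert (not fit.converged) or fit.A < 1.0

    def test_window_smaller_than_3x3_errors(self):
        img = np.zeros((2, 2))
        cand = FocusCandidate(0, (0, 0), np.array([0]), np.array([0]))
        with pytest.raises(ValueError, match="3x3"):
            fit_gaussian(img, cand, window_radius=1)

    def test_noisy_recovery_median_error_below_5pct(self):
        rng = np.random.default_rng(17)
        errs_A, errs_s = [], []
        for _ in range(200):
            A, sigma = 100.0, 2.0
            img = gaussian_image((21, 21), A, 10.0, 10.0, sigma, 20.0)
            img += rng.normal(0, A / 10.0, img.shape)  # SNR 10
            fit = fit_gaussian(img, candidate_at(10, 10), window_radius=8)
            errs_A.append(abs(fit.A - A) / A)
            errs_s.append(abs(fit.sigma - sigma) / sigma)
        assert np.median(errs_A) < 0.05
        assert np.median(errs_s) < 0.05

    def test_border_clipped_fit_flagged(self):
        img = gaussian_image((41, 41), 100.0, 2.0, 2.0, 2.0, 10.0)
        fit = fit_gaussian(img, candidate_at(2, 2), window_radius=6)
        assert fit.clipped


class TestAdaptiveThreshold:
    def _fit(self, A=100.0, sigma=3.0, b=10.0, converged=True):
        from radr.segment import GaussianFit
        return GaussianFit(A=A, x0=0, y0=0, sigma=sigma, b=b, rmse=0.0,
                           converged=converged, window=(0, 10, 0, 10))

    def test_half_maximum_arithmetic(self):
        thr, radius = adaptive_threshold(self._fit())
        assert thr == pytest.approx(60.0)

    def test_analytic_half_max_radius(self):
        _, radius = adaptive_threshold(self._fit(sigma=3.0))
        assert radius == pytest.approx(3.0 * np.sqrt(2 * np.log(2)), rel=1e-9)

    def test_rejection_signals(self):
        assert adaptive_threshold(self._fit(converged=False)) is None
        assert adaptive_threshold(self._fit(A=0.0)) is None
        with pytest.raises(ValueError):
            adaptive_threshold(self._fit(), level_fraction=1.5)


class TestSegmentFocus:
    def test_half_max_area_matches_analytic_disc(self):
        sigma = 3.0
        img = gaussian_image((41, 41), 100.0, 20.0, 20.0, sigma, 10.0)
        cand = candidate_at(20, 20)
        fit = fit_gaussian(img, cand)
        thr, radius = adaptive_threshold(fit)
        region = segment_focus(img, cand, thr, window=fit.window)
        expected = np.pi * (sigma * np.sqrt(2 * np.log(2))) ** 2
        assert region.sum() == pytest.approx(expected, rel=0.15)

    def test_threshold_above_peak_rejects(self):
        img = gaussian_image((21, 21), 50.0, 10.0, 10.0, 2.0, 0.0)
        region = segment_focus(img, candidate_at(10, 10), threshold=200.0)
        assert not region.any()

    def test_two_nearby_foci_segmented_separately(self):
        img = gaussian_image((31, 41), 100.0, 14.0, 15.0, 2.0, 0.0)
        img += gaussian_image((31, 41), 100.0, 26.0, 15.0, 2.0, 0.0)
        cand = candidate_at(15, 14)
        region = segment_focus(img, cand, threshold=50.0)
        assert region[15, 14]
        assert not region[15, 26]  # neighbor's half-max blob excluded

    def test_segmented_area_monotone_in_level_fraction(self):
        img = gaussian_image((41, 41), 100.0, 20.0, 20.0, 3.0, 10.0)
        cand = candidate_at(20, 20)
        fit = fit_gaussian(img, cand)
        areas = []
        for f in [0.2, 0.35, 0.5, 0.65, 0.8]:
            thr, _ = adaptive_threshold(fit, level_fraction=f)
            areas.append(segment_focus(img, cand, thr, window=fit.window).sum())
        assert areas == sorted(areas, reverse=True)


class TestExtractFeatures:
    def _fit(self, b=0.0, A=100.0, sigma=2.0, rmse=0.0):
        from radr.segment import GaussianFit
        return GaussianFit(A=A, x0=0, y0=0, sigma=sigma, b=b, rmse=rmse,
                           converged=True, window=(0, 10, 0, 10))

    def test_single_pixel_region_conventions(self):
        img = np.zeros((9, 9))
        img[4, 4] = 7.0
        mask = img > 0
        feats = extract_features(img, mask, self._fit(b=0.0), noise_sd=1.0)
        assert feats["area"] == 1.0
        assert feats["integrated_intensity"] == 7.0
        assert feats["circularity"] == 1.0

    def test_disc_shape_features(self):
        rr, cc = np.mgrid[0:21, 0:21]
        mask = (rr - 10) ** 2 + (cc - 10) ** 2 <= 25.0
        img = mask.astype(float) * 40.0
        feats = extract_features(img, mask, self._fit(), noise_sd=1.0)
        assert feats["eccentricity"] < 0.1
        # pixel-counting convex hulls bias solidity of small rasterized
        # discs a few percent below 1
        assert feats["solidity"] > 0.90
        assert 0.85 <= feats["circularity"] <= 1.05

    def test_integrated_intensity_half_max_truncation(self):
        # full Gaussian integral is 2*pi*A*sigma^2; segmentation at half
        # maximum keeps exactly half of it
        A, sigma = 100.0, 3.0
        img = gaussian_image((61, 61), A, 30.0, 30.0, sigma, 0.0)
        total = 2 * np.pi * A * sigma**2
        generous = np.ones(img.shape, dtype=bool)
        feats_all = extract_features(img, generous, self._fit(), noise_sd=1.0)
        assert feats_all["integrated_intensity"] == pytest.approx(total, rel=0.01)
        half = img >= 50.0
        feats_half = extract_features(img, half, self._fit(), noise_sd=1.0)
        assert feats_half["integrated_intensity"] == pytest.approx(
            0.5 * total, rel=0.05
        )

    def test_constant_offset_invariance(self):
        rng = np.random.default_rng(3)
        img = gaussian_image((31, 31), 80.0, 15.0, 15.0, 2.5, 20.0)
        mask = img >= 60.0
        f0 = extract_features(img, mask, self._fit(b=20.0), noise_sd=5.0)
        f1 = extract_features(img + 111.0, mask, self._fit(b=131.0), noise_sd=5.0)
        for key, val in f0.items():
            if key in ("peak_intensity", "mean_intensity"):
                assert f1[key] == pytest.approx(val + 111.0)
            elif key == "local_background":
                assert f1[key] == pytest.approx(val + 111.0)
            else:
                assert f1[key] == pytest.approx(val, abs=1e-9)

    def test_empty_region_errors(self):
        with pytest.raises(ValueError, match="empty"):
            extract_features(np.zeros((5, 5)), np.zeros((5, 5), bool),
                             self._fit(), 1.0)
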