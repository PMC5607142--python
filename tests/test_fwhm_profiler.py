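import math

import numpy as np
import pytest

from memgp import (
    ContourPolyline,
    ProfileSamplingParams,
    aggregate_images,
    extract_profile,
    fit_gaussian_profile,
    measure_stack_fwhm,
    profile_image_fwhm,
    render_phantom,
    resample_contour,
    resolution_ratio,
    summarize_fwhm,
)
from memgp.fwhm_profiler import GAUSS_FWHM_FACTOR, GaussianFitResult, LineProfile
from tests.conftest import small_vesicle_spec


def _ridge_image(shape, sigma_px, angle_deg=0.0, offset=10.0, amp=100.0):
    """Analytic Gaussian ridge through the image centre at a given angle."""
    h, w = shape
    yy, xx = np.mgrid[:h, :w].astype(float)
    cx, cy = (w - 1) / 2, (h - 1) / 2
    nx, ny = -math.sin(math.radians(angle_deg)), math.cos(math.radians(angle_deg))
    d = (xx - cx) * nx + (yy - cy) * ny
    return offset + amp * np.exp(-(d**2) / (2 * sigma_px**2))


class TestResampleContour:
    def test_straight_segment_regular_anchors(self):
        c = ContourPolyline(vertices=np.array([[0.0, 0.0], [30.0, 0.0]]))
        pts = resample_contour(c, spacing_px=3)
        assert len(pts) == 11
        np.testing.assert_allclose([p[0][0] for p in pts], np.arange(0, 31, 3))
        for _, (tx, ty) in pts:
            assert (tx, ty) == pytest.approx((1.0, 0.0))

    def test_partial_final_interval_dropped(self):
        c = ContourPolyline(vertices=np.array([[0.0, 0.0], [10.0, 0.0]]))
        pts = resample_contour(c, spacing_px=3)
        assert [p[0][0] for p in pts] == [0.0, 3.0, 6.0, 9.0]

    def test_closed_square_tangents_rotate(self):
        c = ContourPolyline(
            vertices=np.array([[0.0, 0.0], [10.0, 0.0], [10.0, 10.0], [0.0, 10.0]]),
            closed=True,
        )
        pts = resample_contour(c, spacing_px=10.0)
        assert len(pts) == 4
        tangents = np.array([t for _, t in pts])
        # central differences at the corners point along the diagonals
        for t0, t1 in zip(tangents, np.roll(tangents, -1, axis=0)):
            assert abs(np.dot(t0, t1)) < 1e-9  # successive diagonals orthogonal

    def test_circle_tangents_orthogonal_to_radius(self):
        ang = np.linspace(0, 2 * np.pi, 720, endpoint=False)
        c = ContourPolyline(
            vertices=np.column_stack([100 + 100 * np.cos(ang), 100 + 100 * np.sin(ang)]),
            closed=True,
        )
        for (px, py), (tx, ty) in resample_contour(c, spacing_px=3):
            radial = np.array([px - 100, py - 100])
            radial /= np.linalg.norm(radial)
            dot = abs(radial @ np.array([tx, ty]))
            assert dot < math.sin(math.radians(1.0))


class TestExtractProfile:
    def test_constant_image_gives_constant_profile(self):
        img = np.full((50, 50), 7.0)
        prof = extract_profile(img, (25, 25), (1, 0))
        assert not prof.rejected
        np.testing.assert_allclose(prof.intensities, 7.0)
        assert len(prof.positions) == 41
        np.testing.assert_allclose(prof.positions, -prof.positions[::-1])

    def test_analytic_ridge_reproduced_along_normal(self):
        img = _ridge_image((80, 80), sigma_px=4.0)  # ridge runs along x
        prof = extract_profile(img, (39.5, 39.5), (0, 1))
        expected = 10 + 100 * np.exp(-(prof.positions**2) / (2 * 16.0))
        np.testing.assert_allclose(prof.intensities, expected, rtol=5e-3, atol=0.05)

    def test_profile_leaving_image_is_rejected_not_raised(self):
        img = np.zeros((60, 60))
        prof = extract_profile(img, (5, 30), (1, 0))
        assert prof.rejected
        assert np.all(np.isnan(prof.intensities))


class TestGaussianFit:
    def _profile(self, y, L=40):
        x = np.linspace(-L / 2, L / 2, L + 1)
        return LineProfile(anchor=(0, 0), direction=(1, 0), positions=x, intensities=y)

    def test_noiseless_gaussian_recovered_to_closed_form(self):
        x = np.linspace(-20, 20, 41)
        y = 10 + 100 * np.exp(-(x**2) / (2 * 25.0))
        fit = fit_gaussian_profile(self._profile(y), pixel_size_nm=20)
        assert fit.converged
        assert fit.offset == pytest.approx(10, abs=1e-6)
        assert fit.amplitude == pytest.approx(100, abs=1e-6)
        assert fit.center_px == pytest.approx(0, abs=1e-6)
        assert fit.sigma_px == pytest.approx(5, abs=1e-6)
        assert fit.fwhm_px == pytest.approx(GAUSS_FWHM_FACTOR * 5, abs=1e-5)
        assert fit.fwhm_nm == pytest.approx(GAUSS_FWHM_FACTOR * 5 * 20, abs=1e-4)

    def test_flat_profile_not_converged(self):
        fit = fit_gaussian_profile(self._profile(np.full(41, 3.0)))
        assert not fit.converged
        assert fit.reason == "flat profile"

    def test_off_centre_second_membrane_rejected(self):
        # dominant peak far from the anchor: a neighbouring membrane
        x = np.linspace(-20, 20, 41)
        y = 5 + 80 * np.exp(-((x - 15) ** 2) / (2 * 4.0))
        fit = fit_gaussian_profile(self._profile(y))
        assert not fit.converged
        assert fit.reason == "centre outside window"

    def test_bimodal_profile_rejected_by_rules(self):
        x = np.linspace(-20, 20, 41)
        y = (
            60 * np.exp(-((x - 12) ** 2) / (2 * 9.0))
            + 60 * np.exp(-((x + 12) ** 2) / (2 * 9.0))
        )
        fit = fit_gaussian_profile(self._profile(y))
        # either the window rule or a sigma blow-up must reject it
        assert not fit.converged

    def test_rejected_extraction_propagates(self):
        prof = LineProfile((0, 0), (1, 0), np.linspace(-20, 20, 41),
                           np.full(41, np.nan), rejected=True)
        assert not fit_gaussian_profile(prof).converged

    def test_fwhm_oracle_sub_permille_on_analytic_ridges(self):
        """Fitted FWHM matches 2*sqrt(2 ln2)*sigma to <0.1% on clean ridges."""
        ang = math.radians(30.0)
        d = np.array([math.cos(ang), math.sin(ang)])
        c = ContourPolyline(
            vertices=np.vstack([[59.5, 59.5] - 35 * d, [59.5, 59.5] + 35 * d])
        )
        for sigma in (2.5, 4.0, 6.0):
            img = _ridge_image((120, 120), sigma_px=sigma, angle_deg=30.0)
            fits = [f for f in profile_image_fwhm(img, c, pixel_size_nm=1.0)
                    if f.converged]
            assert fits
            for f in fits:
                assert f.fwhm_px == pytest.approx(GAUSS_FWHM_FACTOR * sigma, rel=1e-3)


class TestSummaries:
    def _fit(self, fwhm_px, converged=True):
        return GaussianFitResult(
            offset=0, amplitude=1, center_px=0,
            sigma_px=fwhm_px / GAUSS_FWHM_FACTOR,
            fwhm_px=fwhm_px, fwhm_nm=fwhm_px * 20, converged=converged,
        )

    def test_uniform_fits_mean_and_zero_sd(self):
        s = summarize_fwhm([self._fit(4.0)] * 5, pixel_size_nm=20)
        assert s.mean_fwhm_nm == pytest.approx(80)
        assert s.sd_fwhm_nm == 0
        assert s.n_profiles_used == 5

    def test_rejected_fits_counted_not_averaged(self):
        s = summarize_fwhm([self._fit(4.0), self._fit(9.9, converged=False)])
        assert s.mean_fwhm_nm == pytest.approx(80)
        assert (s.n_profiles_used, s.n_rejected) == (1, 1)

    def test_all_rejected_raises(self):
        with pytest.raises(ValueError, match="no valid profiles"):
            summarize_fwhm([self._fit(4.0, converged=False)])

    def test_resolution_ratio_arithmetic(self):
        conf = summarize_fwhm([self._fit(12.0)] * 3)  # 240 nm
        sted = summarize_fwhm([self._fit(4.0)] * 3)  # 80 nm
        assert resolution_ratio(conf, sted).ratio == pytest.approx(3.0)
        assert resolution_ratio(conf, conf).ratio == pytest.approx(1.0)

    def test_zero_sted_mean_raises(self):
        conf = summarize_fwhm([self._fit(12.0)])
        sted = summarize_fwhm([self._fit(0.0)])
        with pytest.raises(ZeroDivisionError):
            resolution_ratio(conf, sted)


class TestPhantomRecovery:
    def test_noise_free_recovery_within_two_percent(self, sted_vesicle):
        stack, gt, rois = sted_vesicle
        s = measure_stack_fwhm(stack, rois["contour"])
        assert s.mean_fwhm_nm == pytest.approx(gt.psf_fwhm_nm, rel=0.02)

    def test_mean_fwhm_monotone_in_psf_width(self):
        means = []
        for psf in (80.0, 120.0, 240.0):
            stack, _, rois = render_phantom(small_vesicle_spec(psf_fwhm_nm=psf))
            means.append(measure_stack_fwhm(stack, rois["contour"]).mean_fwhm_nm)
        assert means[0] < means[1] < means[2]

    def test_ridge_orientation_changes_fwhm_below_two_percent(self):
        means = []
        for ang in (0.0, 20.0, 45.0, 75.0):
            img = _ridge_image((120, 120), sigma_px=4.0, angle_deg=ang)
            d = np.array([math.cos(math.radians(ang)), math.sin(math.radians(ang))])
            p0 = np.array([59.5, 59.5]) - 40 * d
            p1 = np.array([59.5, 59.5]) + 40 * d
            c = ContourPolyline(vertices=np.vstack([p0, p1]))
            fits = [f for f in profile_image_fwhm(img, c, pixel_size_nm=1.0) if f.converged]
            means.append(np.mean([f.fwhm_px for f in fits]))
        assert (max(means) - min(means)) / min(means) < 0.02

    def test_ratio_above_one_whenever_sted_psf_narrower(self):
        conf_stack, _, rois = render_phantom(small_vesicle_spec(psf_fwhm_nm=240.0))
        sted_stack, _, _ = render_phantom(small_vesicle_spec(psf_fwhm_nm=80.0))
        conf = measure_stack_fwhm(conf_stack, rois["contour"])
        sted = measure_stack_fwhm(sted_stack, rois["contour"])
        assert resolution_ratio(conf, sted).ratio > 1.0
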