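import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from memgp import (
    AxisKind,
    CircleRoi,
    ImageStack,
    PeakMethod,
    SpectrumTrace,
    channel_intensity_ratio,
    extract_spectrum,
    peak_shift,
    peak_wavelength,
    preset,
    recombine_bands,
    render_phantom,
)


def _stack(pages, start=513.0, step=9.0):
    edges = [(start + k * step, start + (k + 1) * step) for k in range(len(pages))]
    return ImageStack(
        pages=[np.asarray(p, float) for p in pages],
        axis_kind=AxisKind.WAVELENGTH,
        band_edges_nm=edges,
    )


def _gauss_windows(peak, sd=25.0, n=20, start=513.0):
    from scipy.special import erf
    edges = [(start + 9 * k, start + 9 * (k + 1)) for k in range(n)]
    s = sd * np.sqrt(2)
    return np.array(
        [0.5 * (erf((hi - peak) / s) - erf((lo - peak) / s)) for lo, hi in edges]
    )


class TestExtractSpectrum:
    def test_uniform_stack_flat_then_normalized(self):
        stack = _stack([np.full((10, 10), 5.0)] * 4)
        roi = CircleRoi(center=(5, 5), radius=3)
        tr = extract_spectrum(stack, roi)
        np.testing.assert_allclose(tr.intensities, 5.0)
        trn = extract_spectrum(stack, roi, normalize=True)
        np.testing.assert_allclose(trn.intensities, 1.0)
        assert trn.normalized

    def test_window_centers_are_band_midpoints(self):
        stack = _stack([np.ones((4, 4))] * 3, start=513.0)
        tr = extract_spectrum(stack, CircleRoi(center=(2, 2), radius=1.5))
        np.testing.assert_allclose(tr.wavelengths_nm, [517.5, 526.5, 535.5])

    def test_roi_outside_image_raises(self):
        stack = _stack([np.ones((10, 10))] * 3)
        with pytest.raises(ValueError, match="no pixels"):
            extract_spectrum(stack, CircleRoi(center=(100, 100), radius=2))

    def test_phantom_ordered_roi_peaks_near_emission_maximum(self):
        spec = preset("spectra-shift", seed=0, noise="none",
                      image_size_px=(160, 160), vesicle_radius_nm=1200.0)
        stack, _, rois = render_phantom(spec)
        tr = extract_spectrum(stack, rois["ordered"], normalize=True)
        brightest = tr.wavelengths_nm[np.argmax(tr.intensities)]
        lo, hi = 570 - 4.5, 570 + 4.5
        assert lo <= brightest <= hi


class TestPeakEstimation:
    def test_single_nonzero_window(self):
        y = np.zeros(9); y[4] = 1.0
        tr = SpectrumTrace(np.arange(555, 555 + 81, 9) + 4.5, y)
        for method in PeakMethod:
            assert peak_wavelength(tr, method).peak_nm == tr.wavelengths_nm[4]

    def test_symmetric_triplet_parabolic_center(self):
        tr = SpectrumTrace(np.array([591.0, 600.0, 609.0]), np.array([0.5, 1.0, 0.5]))
        assert peak_wavelength(tr, "parabolic").peak_nm == pytest.approx(600.0)

    def test_band_integrated_gaussian_within_one_nm_of_dense_oracle(self):
        # dense-grid argmax of the generative spectrum is its 600.0 nm peak
        tr = SpectrumTrace(np.arange(513, 693, 9) + 4.5, _gauss_windows(600.0))
        est = peak_wavelength(tr, "parabolic").peak_nm
        assert est == pytest.approx(600.0, abs=1.0)

    def test_edge_maximum_falls_back_to_bin_center(self):
        tr = SpectrumTrace(np.array([500.0, 509.0, 518.0]), np.array([1.0, 0.5, 0.2]))
        assert peak_wavelength(tr, "parabolic").peak_nm == 500.0

    def test_all_zero_spectrum_raises(self):
        tr = SpectrumTrace(np.array([500.0, 509.0, 518.0]), np.zeros(3))
        with pytest.raises(ValueError, match="all-zero"):
            peak_wavelength(tr)


class TestPeakShift:
    def test_identical_traces_zero_shift(self):
        tr = SpectrumTrace(np.arange(513, 693, 9) + 4.5, _gauss_windows(590.0))
        assert peak_shift(tr, tr) == 0.0

    def test_constructed_40nm_shift(self):
        lam = np.arange(513, 693, 9) + 4.5
        o = SpectrumTrace(lam, _gauss_windows(570.0))
        d = SpectrumTrace(lam, _gauss_windows(610.0))
        assert peak_shift(o, d) == pytest.approx(40.0, abs=1.0)

    @pytest.mark.parametrize("delta", [10.0, 30.0, 50.0])
    def test_shift_recovery_on_nine_nm_windows(self, delta):
        lam = np.arange(450, 750, 9) + 4.5
        o = SpectrumTrace(lam, _gauss_windows(560.0, n=len(lam), start=450.0))
        d = SpectrumTrace(lam, _gauss_windows(560.0 + delta, n=len(lam), start=450.0))
        assert peak_shift(o, d) == pytest.approx(delta, abs=2.0)

    def test_axis_mismatch_raises(self):
        a = SpectrumTrace(np.array([500.0, 509.0, 518.0]), np.ones(3))
        b = SpectrumTrace(np.array([501.0, 510.0, 519.0]), np.ones(3))
        with pytest.raises(ValueError, match="axes"):
            peak_shift(a, b)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_normalization_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        tr = SpectrumTrace(np.arange(513, 594, 9) + 4.5, rng.uniform(0.1, 5, 9))
        once = tr.normalize()
        twice = once.normalize()
        np.testing.assert_allclose(once.intensities, twice.intensities)
        assert once.intensities.max() == pytest.approx(1.0)


class TestChannelRatioAndRecombination:
    def test_identical_rois_ratio_one(self):
        stack = _stack([np.random.default_rng(0).uniform(1, 2, (10, 10))] * 5)
        roi = CircleRoi(center=(5, 5), radius=3)
        for _, r in channel_intensity_ratio(stack, roi, roi):
            assert r == pytest.approx(1.0)

    def test_brighter_ordered_roi_scales_ratio(self):
        page = np.ones((10, 10)); page[:, :5] = 2.0
        stack = _stack([page] * 4)
        left = CircleRoi(center=(2, 5), radius=1.6)
        right = CircleRoi(center=(7, 5), radius=1.6)
        for _, r in channel_intensity_ratio(stack, left, right):
            assert r == pytest.approx(2.0)

    def test_zero_disordered_windows_excluded_with_warning(self):
        pages = [np.ones((6, 6)), np.zeros((6, 6)), np.ones((6, 6))]
        stack = _stack(pages)
        roi = CircleRoi(center=(3, 3), radius=2)
        with pytest.warns(UserWarning, match="excluded 1"):
            out = channel_intensity_ratio(stack, roi, roi)
        assert len(out) == 2

    def test_phantom_ratio_crosses_unity_once(self):
        spec = preset("spectra-shift", seed=0, noise="none",
                      image_size_px=(160, 160), vesicle_radius_nm=1200.0)
        stack, _, rois = render_phantom(spec)
        pairs = channel_intensity_ratio(stack, rois["ordered"], rois["disordered"])
        ratios = np.array([r for _, r in pairs])
        signs = np.sign(ratios - 1.0)
        crossings = np.sum(np.abs(np.diff(signs)) > 0)
        assert signs[0] > 0 and signs[-1] < 0 and crossings == 1

    def test_disjoint_halves_partition_total(self, rng):
        pages = [rng.uniform(0, 3, (8, 8)) for _ in range(6)]
        stack = _stack(pages)
        pair = recombine_bands(stack, (513, 540), (540, 567))
        np.testing.assert_allclose(
            pair.I1 + pair.I2, np.sum(pages, axis=0), rtol=1e-12
        )

    def test_equal_bands_give_identical_channels(self, rng):
        stack = _stack([rng.uniform(0, 3, (8, 8)) for _ in range(4)])
        pair = recombine_bands(stack, (513, 549), (513, 549))
        np.testing.assert_array_equal(pair.I1, pair.I2)

    def test_band_without_windows_raises(self):
        stack = _stack([np.ones((4, 4))] * 3)
        with pytest.raises(ValueError, match="no spectral windows"):
            recombine_bands(stack, (900, 950), (513, 540))

    def test_gfp_lumen_separates_from_membrane_probe(self):
        spec = preset("gfp-gpmv", seed=0, noise="none",
                      image_size_px=(160, 160), vesicle_radius_nm=1200.0)
        spec.extra_objects[0].center_px = (79.5, 79.5)
        spec.extra_objects[0].diameter_nm = 2200.0
        stack, _, rois = render_phantom(spec)
        pair = recombine_bands(stack, (500, 530), (570, 693))
        h, w = stack.shape
        lumen = pair.I1[h // 2, w // 2], pair.I2[h // 2, w // 2]
        ring = int(round(h / 2 + 1200.0 / 20.0))
        membrane = pair.I1[ring, w // 2], pair.I2[ring, w // 2]
        assert lumen[0] > 10 * max(lumen[1], 1e-9)  # GFP confined to band a
        assert membrane[1] > 10 * max(membrane[0], 1e-9)  # probe in band b
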