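"""Unit and property tests for the calibrated spectral-analysis chain."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from qus.spectral import (
    CalibratedSpectrum,
    PowerSpectrum,
    ROISpec,
    analysis_band,
    average_spectral_params,
    calibrate,
    depth_to_sample,
    fit_spectral_params,
    gate_roi,
    percent_change,
    tumor_spectral_params,
    windowed_power_spectrum,
)
from qus.synthetic_rf import RFFrame, simulate_tissue_frame


def _line_spectrum(slope, intercept, f_lo=3.0, f_hi=9.0, n=40):
    f = np.linspace(f_lo, f_hi, n)
    return CalibratedSpectrum(frequencies=f, magnitude_db=slope * f + intercept, band=(f_lo, f_hi))


class TestFitSpectralParams:
    @settings(derandomize=True, max_examples=60)
    @given(
        slope=st.floats(-15, 5),
        intercept=st.floats(-80, 0),
        f_lo=st.floats(2, 5),
        width=st.floats(1, 8),
    )
    def test_exact_line_is_recovered_to_numerical_precision(self, slope, intercept, f_lo, width):
        spec = _line_spectrum(slope, intercept, f_lo, f_lo + width)
        params = fit_spectral_params(spec)
        fc = 0.5 * (spec.band[0] + spec.band[1])
        assert params.slope == pytest.approx(slope, abs=1e-9)
        assert params.midband == pytest.approx(slope * fc + intercept, abs=1e-9)
        assert params.intercept == pytest.approx(intercept, abs=1e-8)

    def test_constant_spectrum_has_zero_slope(self):
        params = fit_spectral_params(_line_spectrum(0.0, -20.0))
        assert params.slope == pytest.approx(0.0, abs=1e-12)
        assert params.midband == pytest.approx(-20.0, abs=1e-12)

    def test_symmetric_zigzag_perturbation_leaves_slope_nearly_unbiased(self):
        f = np.linspace(4.0, 8.0, 40)
        zigzag = np.where(np.arange(40) % 2 == 0, 1.0, -1.0)
        spec = CalibratedSpectrum(f, 3.0 * f - 30.0 + zigzag, band=(4.0, 8.0))
        # independent oracle: normal equations on the same grid
        design = np.column_stack([f, np.ones_like(f)])
        expected_slope, _ = np.linalg.lstsq(design, spec.magnitude_db, rcond=None)[0]
        params = fit_spectral_params(spec)
        assert params.slope == pytest.approx(expected_slope, abs=1e-9)
        assert abs(params.slope - 3.0) < 0.05

    def test_fewer_than_three_bins_rejected(self):
        f = np.array([4.0, 5.0, 6.0, 7.0])
        spec = CalibratedSpectrum(f, np.zeros(4), band=(4.0, 4.5))
        with pytest.raises(ValueError, match="fewer than 3"):
            fit_spectral_params(spec)


class TestGateROI:
    def _frame(self, n_lines=64, n_samples=2048):
        return RFFrame(lines=np.zeros((n_lines, n_samples)), sampling_rate=35.0)

    def test_returns_requested_number_of_lines(self):
        segments = gate_roi(self._frame(), ROISpec(10.0, 4.0, first_line=10, n_lines=8))
        assert segments.shape[0] == 8

    def test_depth_maps_to_floor_of_two_way_travel(self):
        frame = self._frame()
        roi = ROISpec(10.0, 4.0, 0, 4)
        start = depth_to_sample(10.0, frame.sound_speed, frame.sampling_rate)
        assert start == int(np.floor(2 * 10.0 / 1.54 * 35.0))
        stop = depth_to_sample(14.0, frame.sound_speed, frame.sampling_rate)
        assert gate_roi(frame, roi).shape[1] == stop - start

    @pytest.mark.parametrize(
        "roi, message",
        [
            (ROISpec(40.0, 10.0, 0, 4), "samples"),
            (ROISpec(10.0, 4.0, 60, 10), "lines"),
        ],
    )
    def test_roi_outside_frame_names_offending_bound(self, roi, message):
        with pytest.raises(ValueError, match=message):
            gate_roi(self._frame(), roi)


class TestWindowedPowerSpectrum:
    def test_all_ones_segment_matches_closed_form_hamming_spectrum(self):
        # independent oracle: geometric-series closed form of the symmetric
        # Hamming window DFT, w[n] = 0.54 - 0.46 cos(2 pi n / (L-1))
        length, fs = 128, 35.0
        result = windowed_power_spectrum(np.ones((1, length)), fs)

        def geometric(alpha, k):
            z = np.exp(1j * (alpha - 2 * np.pi * k / length))
            if abs(z - 1) < 1e-15:
                return complex(length)
            return (1 - z**length) / (1 - z)

        for k in (1, 2, 3, 5, 20):
            a = 2 * np.pi / (length - 1)
            w_k = 0.54 * geometric(0.0, k) - 0.23 * (geometric(a, k) + geometric(-a, k))
            expected_db = 10 * np.log10(abs(w_k) ** 2)
            assert result.magnitude_db[k - 1] == pytest.approx(expected_db, abs=1e-9)

    def test_pure_sinusoid_peaks_at_its_bin(self):
        length, fs, k = 256, 35.0, 40
        t = np.arange(length)
        seg = np.sin(2 * np.pi * k * t / length)
        result = windowed_power_spectrum(seg[None, :], fs)
        assert np.argmax(result.magnitude_db) == k - 1  # DC bin dropped

    def test_averaging_identical_segments_is_identity(self):
        rng = np.random.default_rng(0)
        seg = rng.normal(size=128)
        one = windowed_power_spectrum(seg[None, :], 35.0)
        two = windowed_power_spectrum(np.vstack([seg, seg]), 35.0)
        np.testing.assert_allclose(one.magnitude_db, two.magnitude_db, atol=1e-12)
        assert two.n_lines_averaged == 2

    def test_all_zero_segments_hit_floor_with_warning(self):
        with pytest.warns(RuntimeWarning, match="floor"):
            result = windowed_power_spectrum(np.zeros((2, 128)), 35.0)
        assert np.all(result.magnitude_db == -300.0)

    def test_short_gate_rejected(self):
        with pytest.raises(ValueError, match="gate length"):
            windowed_power_spectrum(np.ones((1, 32)), 35.0)


class TestCalibrate:
    def _spectrum(self, mag):
        f = np.linspace(1.0, 17.0, mag.size)
        return PowerSpectrum(f, mag, 1)

    def test_self_calibration_is_identically_zero(self):
        mag = -30.0 + 10.0 * np.exp(-((np.linspace(1, 17, 80) - 6) ** 2))
        spec = self._spectrum(mag)
        cal = calibrate(spec, spec, band=(4.0, 8.0))
        assert np.all(cal.magnitude_db == 0.0)
        params = fit_spectral_params(cal)
        assert params.slope == pytest.approx(0.0, abs=1e-12)
        assert params.midband == pytest.approx(0.0, abs=1e-12)

    def test_reference_gain_shifts_calibrated_level_linearly_in_db(self):
        mag = -30.0 + 10.0 * np.exp(-((np.linspace(1, 17, 80) - 6) ** 2))
        tissue, louder_ref = self._spectrum(mag), self._spectrum(mag + 6.02)
        cal = calibrate(tissue, louder_ref, band=(4.0, 8.0))
        np.testing.assert_allclose(cal.magnitude_db, -6.02, atol=1e-12)

    def test_mismatched_grids_rejected(self):
        a = self._spectrum(np.zeros(80))
        b = PowerSpectrum(np.linspace(1, 17, 64), np.zeros(64), 1)
        with pytest.raises(ValueError, match="grid"):
            calibrate(a, b)


class TestAnalysisBand:
    def _gaussian_reference(self, fc=6.0, sigma=1.2745, n=400):
        f = np.linspace(0.1, 17.5, n)
        mag_db = 20 * np.log10(np.exp(-((f - fc) ** 2) / (2 * sigma**2)))
        return PowerSpectrum(f, mag_db, 1)

    def test_threshold_6dB_recovers_half_amplitude_bandwidth_of_gaussian(self):
        # closed form: amplitude Gaussian with sigma_f falls to half amplitude
        # (-6.02 dB power) at +/- sigma_f sqrt(2 ln 2)
        sigma = 1.2745
        ref = self._gaussian_reference(sigma=sigma)
        lo, hi = analysis_band(ref, threshold_db=6.02)
        expected = 2 * sigma * np.sqrt(2 * np.log(2))
        bin_width = ref.frequencies[1] - ref.frequencies[0]
        assert hi - lo == pytest.approx(expected, abs=2 * bin_width)

    def test_zero_threshold_band_is_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            analysis_band(self._gaussian_reference(), threshold_db=0.0)

    def test_monotone_spectrum_has_no_interior_peak(self):
        f = np.linspace(1.0, 10.0, 50)
        ref = PowerSpectrum(f, -2.0 * f, 1)
        with pytest.raises(ValueError, match="interior peak"):
            analysis_band(ref)


class TestTumorSpectralParams:
    def test_three_identical_rois_equal_single_roi_result(
        self, pulse, reference, control_response, roi_plan
    ):
        frame = simulate_tissue_frame(pulse, control_response, seed=0)
        roi = roi_plan[0]
        mean_params, per_roi = tumor_spectral_params(frame, reference, [roi, roi, roi])
        assert mean_params.slope == pytest.approx(per_roi[0].slope, abs=1e-12)
        assert mean_params.midband == pytest.approx(per_roi[0].midband, abs=1e-12)

    def test_average_of_params_is_arithmetic_mean(self):
        band, fc = (4.0, 8.0), 6.0
        params = [
            fit_spectral_params(_line_spectrum(s, m - s * fc, *band))
            for s, m in [(-9.0, -50.0), (-10.0, -55.0), (-11.0, -60.0)]
        ]
        mean = average_spectral_params(params)
        assert mean.slope == pytest.approx(-10.0, abs=1e-9)
        assert mean.midband == pytest.approx(-55.0, abs=1e-9)
        assert mean.midband == pytest.approx(mean.slope * fc + mean.intercept, abs=1e-9)

    def test_rf_gain_shifts_midband_but_not_slope(
        self, pulse, reference, control_response, roi_plan
    ):
        frame = simulate_tissue_frame(pulse, control_response, seed=4)
        scaled = RFFrame(
            lines=np.asarray(frame.lines, dtype=float) * 2.0,
            sampling_rate=frame.sampling_rate,
            line_pitch=frame.line_pitch,
            sound_speed=frame.sound_speed,
            kind=frame.kind,
        )
        base, _ = tumor_spectral_params(frame, reference, roi_plan)
        amplified, _ = tumor_spectral_params(scaled, reference, roi_plan)
        assert amplified.midband - base.midband == pytest.approx(20 * np.log10(2), abs=0.1)
        assert amplified.slope - base.slope == pytest.approx(0.0, abs=0.05)

    def test_white_noise_frames_have_zero_expected_calibrated_slope(self, reference, roi_plan):
        rng = np.random.default_rng(123)
        slopes = []
        for _ in range(30):
            frame = RFFrame(lines=rng.normal(size=(120, 1364)), sampling_rate=35.0)
            params, _ = tumor_spectral_params(frame, reference, roi_plan)
            slopes.append(params.slope)
        mean = np.mean(slopes)
        sem = np.std(slopes, ddof=1) / np.sqrt(len(slopes))
        assert abs(mean) < max(4 * sem, 0.05)


class TestPercentChange:
    @pytest.mark.parametrize(
        "control, treated, expected",
        [(-10.66, -5.49, 48.5), (-57.10, -49.81, 12.8), (3.0, 3.0, 0.0)],
    )
    def test_reported_group_shifts(self, control, treated, expected):
        assert percent_change(control, treated) == pytest.approx(expected, abs=0.05)

    def test_zero_control_mean_rejected(self):
        with pytest.raises(ValueError):
            percent_change(0.0, 1.0)

    @settings(derandomize=True, max_examples=40)
    @given(
        control=st.floats(-100, 100).filter(lambda v: abs(v) > 1e-6),
        treated=st.floats(-100, 100),
    )
    def test_sign_matches_direction_of_change(self, control, treated):
        pc = percent_change(control, treated)
        assert np.sign(pc) == np.sign(treated - control)
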