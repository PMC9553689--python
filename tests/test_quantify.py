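import numpy as np
import pytest

from nutspec import datasets, quantify as q
from nutspec.synthetic import generate_standard_series


class TestFitCalibration:
    def test_two_points_interpolated_exactly(self):
        series = q.StandardSeries("x", [100.0, 200.0], [250.0, 450.0])
        curve = q.fit_calibration(series)
        assert curve.slope == pytest.approx(2.0)
        assert curve.intercept == pytest.approx(50.0)
        assert curve.r_squared == pytest.approx(1.0)

    def test_monte_carlo_r2_at_calibrated_noise(self):
        """12-level 100-1200 ppm series with small noise: R^2 > 0.99 in >= 95% of seeds."""
        levels = list(np.linspace(100, 1200, 12))
        hits = 0
        for seed in range(1000):
            series = generate_standard_series("sucrose", 2.0, 5.0, levels,
                                              noise_sd=40.0, seed=seed)
            if q.fit_calibration(series).r_squared > 0.99 :
                hits += 1
        assert hits >= 950

    def test_log_log_recovers_power_law(self):
        levels = np.linspace(100, 1200, 8)
        responses = 0.5 * levels**1.6
        curve = q.fit_calibration(q.StandardSeries("x", levels, responses), log_log=True)
        assert curve.slope == pytest.approx(1.6, abs=1e-9)
        assert q.back_calculate_ppm(curve, 0.5 * 500**1.6) == pytest.approx(500.0)

    def test_identical_levels_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            q.StandardSeries("x", [100.0, 100.0], [1.0, 2.0])


class TestAssignPeaks:
    def test_sucrose_window(self):
        peaks = q.assign_peaks([q.PeakRecord(19.10, 100.0)], q.SUGAR_LIBRARY, 0.2)
        assert peaks[0].analyte == "sucrose"

    def test_out_of_window_unassigned(self):
        peaks = q.assign_peaks([q.PeakRecord(15.0, 100.0)], q.SUGAR_LIBRARY, 0.2)
        assert peaks[0].analyte is None

    def test_exact_library_times_all_assigned_in_order(self):
        rts = q.SUGAR_LIBRARY.retention_times
        peaks = q.assign_peaks(
            [q.PeakRecord(rt, 1.0) for rt in rts.values()], q.SUGAR_LIBRARY
        )
        assert [p.analyte for p in peaks] == list(rts)

    def test_monosaccharides_elute_before_disaccharides(self):
        rts = q.SUGAR_LIBRARY.retention_times
        monos = ["xylose", "fructose", "galactose", "glucose"]
        dis = ["sucrose", "lactose", "maltose"]
        assert max(rts[m] for m in monos) < min(rts[d] for d in dis)

    def test_nearest_peak_wins_conflict(self):
        peaks = q.assign_peaks(
            [q.PeakRecord(19.00, 1.0), q.PeakRecord(19.09, 2.0)], q.SUGAR_LIBRARY, 0.15
        )
        assert peaks[0].analyte is None
        assert peaks[1].analyte == "sucrose"

    def test_overlapping_windows_rejected_at_configuration(self):
        # sorbitol and galactose are 0.85 min apart
        with pytest.raises(ValueError, match="overlap"):
            q.assign_peaks([q.PeakRecord(10.0, 1.0)], q.SUGAR_LIBRARY, tolerance=0.5)


class TestQuantifySample:
    def _curve(self, analyte="sucrose", slope=2.0, intercept=5.0):
        return q.CalibrationCurve(analyte, slope, intercept, 1.0, (100.0, 1200.0))

    def test_blank_area_gives_zero(self):
        peaks = [q.PeakRecord(19.08, 5.0, "sucrose")]  # area equals the intercept
        table = q.quantify_sample(peaks, {"sucrose": self._curve()}, 1.0, 10.0)
        assert table["ppm_extract"].iloc[0] == pytest.approx(0.0)
        assert "below_range" in table["flags"].iloc[0]

    def test_forward_inverse_arithmetic(self):
        """A 500 ppm extract from 1 g in 10 mL is 500 mg/100 g flour."""
        area = 2.0 * 500.0 + 5.0
        peaks = [q.PeakRecord(19.08, area, "sucrose")]
        table = q.quantify_sample(peaks, {"sucrose": self._curve()}, 1.0, 10.0)
        assert table["ppm_extract"].iloc[0] == pytest.approx(500.0, abs=1e-9)
        assert table["amount_per_100g"].iloc[0] == pytest.approx(500.0, abs=1e-9)
        assert table["unit"].iloc[0] == "mg/100 g flour"

    def test_oil_basis_reports_micrograms(self):
        curve = q.CalibrationCurve("resveratrol", 1000.0, 0.0, 1.0, (0.001, 1.0))
        peaks = [q.PeakRecord(3.05, 0.02, "resveratrol")]
        table = q.quantify_sample(peaks, {"resveratrol": curve}, 1.0, 10.0, basis="oil")
        # 2e-5 mg/L extract -> 2e-7 mg in 10 mL -> 2e-5 mg/100 g -> 0.02 ug/100 g
        assert table["amount_per_100g"].iloc[0] == pytest.approx(0.02)
        assert table["unit"].iloc[0] == "ug/100 g oil"

    def test_doubling_volume_doubles_amount(self):
        area = 2.0 * 300.0 + 5.0
        peaks = [q.PeakRecord(19.08, area, "sucrose")]
        curves = {"sucrose": self._curve()}
        a = q.quantify_sample(peaks, curves, 1.0, 10.0)["amount_per_100g"].iloc[0]
        b = q.quantify_sample(peaks, curves, 1.0, 20.0)["amount_per_100g"].iloc[0]
        assert b == pytest.approx(2 * a)

    def test_negative_concentration_flagged_zero(self):
        peaks = [q.PeakRecord(19.08, 1.0, "sucrose")]  # below intercept
        with pytest.warns(UserWarning, match="< 0"):
            table = q.quantify_sample(peaks, {"sucrose": self._curve()}, 1.0, 10.0)
        assert table["amount_per_100g"].iloc[0] == 0.0
        assert "below_zero" in table["flags"].iloc[0]

    def test_extrapolation_flagged(self):
        area = 2.0 * 2000.0 + 5.0
        peaks = [q.PeakRecord(19.08, area, "sucrose")]
        table = q.quantify_sample(peaks, {"sucrose": self._curve()}, 1.0, 10.0)
        assert "above_range" in table["flags"].iloc[0]

    def test_generator_inversion_roundtrip(self):
        """Noiseless synthetic responses back-calculate to the true ppm."""
        series = generate_standard_series("glucose", 3.3, -7.0, [100, 400, 800, 1200])
        curve = q.fit_calibration(series)
        for true_ppm in (150.0, 500.0, 1100.0):
            area = 3.3 * true_ppm - 7.0
            assert q.back_calculate_ppm(curve, area) == pytest.approx(true_ppm, abs=1e-9)

    def test_missing_curve_rejected(self):
        peaks = [q.PeakRecord(19.08, 10.0, "sucrose")]
        with pytest.raises(ValueError, match="no calibration curve"):
            q.quantify_sample(peaks, {}, 1.0, 10.0)


class TestPublishedSugarTotals:
    def test_per_sample_totals_span_printed_range(self):
        totals = datasets.sugar_concentrations().sum(axis=1)
        assert totals.min() == pytest.approx(913.64, abs=0.01)
        assert totals.max() == pytest.approx(5055.51, abs=0.01)
        assert totals.idxmin() == "bkb" and totals.idxmax() == "inc"
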