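import numpy as np
import pytest

from oxiraman.calibration import (
    CalibrationCurve,
    LinearCalibration,
    average_calibration,
    build_calibration,
    detection_limit,
    predict_concentration,
)
from oxiraman.exceptions import DesignError

CONC = np.array([0.0, 1.0, 2.0, 4.0, 8.0, 16.0])


def _exact_curve(slope=0.008, intercept=0.0, correct_c0=True, sigma=None):
    areas = slope * CONC + intercept
    curve = build_calibration(list(zip(CONC, areas)), correct_c0=correct_c0)
    if sigma is not None:
        curve = CalibrationCurve(
            label=curve.label, slope=curve.slope, slope_se=curve.slope_se,
            intercept=curve.intercept, intercept_se=curve.intercept_se,
            sigma_res=sigma, concentrations=curve.concentrations,
            areas=curve.areas, c0_corrected=curve.c0_corrected,
        )
    return curve


class TestBuildCalibration:
    def test_exact_line_through_origin(self):
        curve = _exact_curve(0.008)
        assert abs(curve.slope - 0.008) < 1e-12
        assert curve.intercept == 0.0
        assert curve.sigma_res < 1e-12

    def test_intercept_removed_by_c0_correction(self):
        curve = _exact_curve(0.009, intercept=0.01)
        assert abs(curve.slope - 0.009) < 1e-12
        assert curve.intercept == 0.0  # zero by construction
        assert curve.sigma_res < 1e-12

    def test_uncorrected_fit_keeps_intercept(self):
        curve = _exact_curve(0.009, intercept=0.01, correct_c0=False)
        assert abs(curve.intercept - 0.01) < 1e-12

    def test_monte_carlo_slope_unbiased_and_se_calibrated(self):
        rng = np.random.default_rng(2024)
        sigma, true_slope = 0.002, 0.008
        slopes, ses = [], []
        for _ in range(200):
            areas = true_slope * CONC + rng.normal(0.0, sigma, CONC.size)
            c = LinearCalibration(CONC, areas, correct_c0=True).fit()
            slopes.append(c.slope)
            ses.append(c.slope_se)
        slopes = np.array(slopes)
        sem = slopes.std(ddof=1) / np.sqrt(slopes.size)
        assert abs(slopes.mean() - true_slope) < 3 * sem
        assert abs(np.mean(ses) / slopes.std(ddof=1) - 1.0) < 0.2

    def test_design_errors(self):
        with pytest.raises(DesignError, match="distinct"):
            build_calibration([(0.0, 0.0), (1.0, 0.1), (1.0, 0.1)])
        with pytest.raises(DesignError):
            build_calibration([(2.0, 0.1), (2.0, 0.2), (2.0, 0.15)])


class TestAverageCalibration:
    def test_identical_curves_average_to_themselves(self):
        a = _exact_curve(0.008)
        avg = average_calibration(a, a)
        assert abs(avg.slope - a.slope) < 1e-15
        assert avg.c0_corrected

    def test_average_lies_between_slopes(self):
        avg = average_calibration(_exact_curve(0.008), _exact_curve(0.009))
        assert 0.008 <= avg.slope <= 0.009

    def test_precise_curve_dominates(self):
        kw = dict(intercept=0.0, intercept_se=0.0, sigma_res=0.001,
                  concentrations=CONC, areas=0.008 * CONC, c0_corrected=True)
        a = CalibrationCurve(label="A", slope=0.008, slope_se=1e-6, **kw)
        b = CalibrationCurve(label="B", slope=0.009, slope_se=1e-2, **kw)
        avg = average_calibration(a, b)
        assert abs(avg.slope - 0.008) < 1e-5

    def test_mismatched_designs_rejected(self):
        a = _exact_curve(0.008)
        other = build_calibration(
            [(0.0, 0.0), (5.0, 0.04), (10.0, 0.08), (20.0, 0.16)], correct_c0=True
        )
        with pytest.raises(DesignError, match="differ"):
            average_calibration(a, other)

    def test_uncorrected_curves_rejected(self):
        a = _exact_curve(0.008)
        b = _exact_curve(0.008, correct_c0=False)
        with pytest.raises(DesignError, match="C0"):
            average_calibration(a, b)


class TestPrediction:
    def test_exact_inversion(self):
        curve = _exact_curve(0.008)
        est = predict_concentration(curve, 0.064)
        assert abs(est.value - 8.0) < 1e-9
        assert not est.below_range and not est.above_range

    def test_zero_area_gives_sigma_over_slope_uncertainty(self):
        curve = _exact_curve(0.008, sigma=0.0024)
        est = curve.predict(0.0)
        assert est.value == 0.0
        assert abs(est.uncertainty - 0.0024 / 0.008) < 1e-9

    def test_roundtrip_identity_on_noiseless_line(self):
        curve = _exact_curve(0.009, intercept=0.01)
        for c in (0.5, 3.0, 12.0):
            est = curve.predict(curve.slope * c + curve.intercept)
            assert abs(est.value - c) < 1e-9

    def test_negative_estimate_flagged_not_clipped(self):
        curve = _exact_curve(0.008, sigma=0.001)
        est = curve.predict(-0.01)
        assert est.value < 0
        assert est.below_range

    def test_zero_slope_rejected(self):
        curve = _exact_curve(0.008)
        flat = CalibrationCurve(
            label="flat", slope=0.0, slope_se=0.0, intercept=0.0, intercept_se=0.0,
            sigma_res=0.0, concentrations=curve.concentrations, areas=curve.areas,
        )
        with pytest.raises(ZeroDivisionError):
            flat.predict(0.1)

    def test_monte_carlo_recovery_and_coverage_at_5pct(self):
        rng = np.random.default_rng(77)
        sigma, slope, true_c = 0.002, 0.008, 5.0
        design = np.tile(CONC, 3)  # triplicate design, as measured in practice
        values, covered = [], 0
        n = 100
        for _ in range(n):
            areas = slope * design + rng.normal(0.0, sigma, design.size)
            curve = LinearCalibration(design, areas, correct_c0=True).fit()
            unknown = slope * true_c + rng.normal(0.0, sigma)
            est = curve.predict(unknown)
            values.append(est.value)
            covered += abs(est.value - true_c) <= 1.96 * est.uncertainty
        values = np.array(values)
        sem = values.std(ddof=1) / np.sqrt(n)
        assert abs(values.mean() - true_c) < 3 * sem
        assert covered / n >= 0.90


class TestDetectionLimit:
    def test_zero_noise_gives_zero_lod(self):
        assert detection_limit(_exact_curve(0.008)) < 1e-10

    def test_formula_at_documented_scatter(self):
        curve = _exact_curve(0.008, sigma=0.0024)
        assert abs(curve.detection_limit(k=3.3) - 0.99) < 1e-9

    def test_homogeneous_in_sigma_and_inverse_in_slope(self):
        base = _exact_curve(0.008, sigma=0.001).detection_limit()
        assert np.isclose(_exact_curve(0.008, sigma=0.002).detection_limit(), 2 * base)
        assert np.isclose(_exact_curve(0.016, sigma=0.001).detection_limit(), base / 2)

    def test_nonpositive_slope_rejected(self):
        curve = _exact_curve(0.008)
        bad = CalibrationCurve(
            label="bad", slope=-0.01, slope_se=0.0, intercept=0.0, intercept_se=0.0,
            sigma_res=0.001, concentrations=curve.concentrations, areas=curve.areas,
        )
        with pytest.raises(ValueError):
            bad.detection_limit()
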