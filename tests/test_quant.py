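"""External-standard calibration, LOD/LOQ and validation metrics."""

import numpy as np
import pytest

from ginsquant.chrom import extract_xic, estimate_noise, integrate_peak
from ginsquant.library import get_analyte
from ginsquant.quant import (CalibrationCurve, fit_curve,
                             gaussian_height_per_area, lod_loq,
                             precision_accuracy, quantify_esm, rsd,
                             stability_series)
from ginsquant.synthetic import SyntheticRunConfig, make_sample_run

RG1_LEVELS = (0.02, 0.05, 0.1, 0.2, 0.5, 1.0, 2.0)


class TestFitCurve:
    def test_exact_line_recovered(self):
        pts = [(x, 64984 * x + 980287) for x in RG1_LEVELS]
        curve = fit_curve(pts, analyte="Rg1")
        assert curve.slope == pytest.approx(64984, rel=1e-12)
        assert curve.intercept == pytest.approx(980287, rel=1e-12)
        assert curve.r2 == pytest.approx(1.0, abs=1e-12)

    def test_unit_line(self):
        curve = fit_curve([(0, 0), (1, 1), (2, 2)])
        assert (curve.slope, curve.intercept) == (1.0, 0.0)
        assert curve.r2 == pytest.approx(1.0)

    def test_consistency_under_symmetric_noise(self, rng):
        x = rng.uniform(0.1, 2.0, 10_000)
        y = 500.0 * x + 20.0 + rng.normal(0, 5.0, x.size)
        curve = fit_curve(list(zip(x, y)))
        assert curve.slope == pytest.approx(500.0, rel=0.01)

    def test_through_origin(self):
        pts = [(x, 123.0 * x) for x in (0.1, 0.2, 0.5)]
        curve = fit_curve(pts, through_origin=True)
        assert curve.intercept == 0.0
        assert curve.slope == pytest.approx(123.0, rel=1e-12)

    def test_constant_concentration_rejected(self):
        with pytest.raises(ValueError):
            fit_curve([(1.0, 2.0), (1.0, 3.0), (1.0, 4.0)])

    def test_negative_slope_warns(self):
        with pytest.warns(UserWarning, match="slope"):
            fit_curve([(0, 3.0), (1, 2.0), (2, 1.0)])


class TestLodLoq:
    def test_closed_form_and_ratio(self):
        # pick noise so that the detection limit lands at 0.032 ng/mL;
        # the quantification limit must then be 10/3 of it
        curve = CalibrationCurve("Rg1", 64984.0, 980287.0, 1.0, (0.02, 2.0))
        hpa = gaussian_height_per_area(0.05)
        noise = 0.032e-3 * curve.slope * hpa / 3.0
        lod, loq = lod_loq(curve, noise, hpa)
        assert lod == pytest.approx(0.032, rel=1e-9)
        assert loq == pytest.approx(0.032 * 10 / 3, rel=1e-9)

    def test_linearity_in_noise(self):
        curve = CalibrationCurve("x", 1000.0, 0.0, 1.0, (0.01, 1.0))
        hpa = gaussian_height_per_area(0.05)
        lod1, loq1 = lod_loq(curve, 5.0, hpa)
        lod2, loq2 = lod_loq(curve, 10.0, hpa)
        assert lod2 == pytest.approx(2 * lod1)
        assert loq2 == pytest.approx(2 * loq1)

    def test_nonpositive_inputs_rejected(self):
        curve = CalibrationCurve("x", 1000.0, 0.0, 1.0, (0.01, 1.0))
        with pytest.raises(ValueError):
            lod_loq(curve, 0.0, 1.0)

    def test_simulated_peak_at_lod_has_snr_near_three(self, library):
        """Round trip: generate at the computed detection limit and measure
        S/N from the chromatogram (mean over seeds, +/-30%)."""
        spec = get_analyte("Rd", library)
        sigma = 0.05
        hpa = gaussian_height_per_area(sigma)
        baseline_sd = 50.0
        curve = CalibrationCurve("Rd", spec.slope, 0.0, 1.0, spec.cal_range)
        lod_ng, _ = lod_loq(curve, baseline_sd, hpa)
        conc = lod_ng / 1000.0
        ratios = []
        for seed in range(8):
            cfg = SyntheticRunConfig(seed=seed, zero_intercept=True,
                                     baseline_sd=baseline_sd)
            run = make_sample_run(library, {"Rd": conc}, cfg)
            xic = extract_xic(run, spec.mz, 20.0)
            noise = estimate_noise(
                xic, exclude=[(spec.rt_min - 0.4, spec.rt_min + 0.4)])
            peak = integrate_peak(
                xic, (spec.rt_min - 0.2, spec.rt_min + 0.2), noise=noise)
            ratios.append(peak.snr)
        assert np.mean(ratios) == pytest.approx(3.0, rel=0.30)


class TestQuantify:
    def test_inverts_reported_line(self):
        curve = CalibrationCurve("Rg1", 64984.0, 980287.0, 1.0, (0.02, 2.0))
        assert quantify_esm(1045271.0, curve) == pytest.approx(1.0, rel=1e-9)

    def test_area_equal_intercept_gives_zero(self):
        curve = CalibrationCurve("Rg1", 64984.0, 980287.0, 1.0, (0.02, 2.0))
        with pytest.warns(UserWarning):
            assert quantify_esm(980287.0, curve) == 0.0

    def test_negative_concentration_flagged_not_clamped(self):
        curve = CalibrationCurve("x", 100.0, 50.0, 1.0, (0.01, 1.0))
        with pytest.warns(UserWarning, match="negative"):
            conc = quantify_esm(0.0, curve)
        assert conc == pytest.approx(-0.5)

    def test_roundtrip_identity_on_noise_free_truth(self, library):
        """generate-at-C then quantify equals C exactly when the area
        dispersion is off."""
        cfg = SyntheticRunConfig(seed=0, zero_intercept=True)
        spec = get_analyte("CY", library)
        run = make_sample_run(library, {"CY": 0.123}, cfg)
        curve = CalibrationCurve("CY", spec.slope, 0.0, 1.0, spec.cal_range)
        conc = quantify_esm(run.truth["CY"]["area"], curve)
        assert conc == pytest.approx(0.123, rel=1e-12)


class TestCalibrationOnSyntheticSeries:
    def test_noise_free_series_reproduces_library_law(self, library):
        from ginsquant.pipeline import calibrate
        cfg = SyntheticRunConfig(seed=0, zero_intercept=True)
        curves = calibrate(library, cfg, n_injections=1)
        for spec in library:
            curve = curves[spec.name]
            assert curve.r2 == pytest.approx(1.0, abs=1e-9)
            # window truncation and isobaric clipping keep the measured
            # response within 1% of the generating slope
            assert curve.slope == pytest.approx(spec.slope, rel=0.01)

    def test_noisy_series_keeps_r2_above_reported_floor(self, library):
        from ginsquant.pipeline import calibrate
        cfg = SyntheticRunConfig(seed=1, area_cv=0.02, zero_intercept=True)
        curves = calibrate(library, cfg)
        assert all(c.r2 >= 0.99 for c in curves.values())


class TestValidationMetrics:
    def test_reported_replicate_series_rsd(self):
        # worked replicate series from the reported response-factor table
        prec, _ = precision_accuracy([0.32, 0.30, 0.31, 0.30, 0.30],
                                     target=0.306)
        assert prec == pytest.approx(2.92, abs=0.005)
        prec2, _ = precision_accuracy([3.45, 3.25, 3.05, 3.18, 3.22],
                                      target=3.23)
        assert prec2 == pytest.approx(4.48, abs=0.005)

    def test_identical_replicates(self):
        prec, re = precision_accuracy([0.2] * 6, target=0.2)
        assert prec == pytest.approx(0.0, abs=1e-9)
        assert re == pytest.approx(0.0, abs=1e-9)

    def test_stability_constant_series(self):
        assert stability_series([100.0] * 6) == 0.0

    def test_stability_envelope_at_two_percent_cv(self, library):
        rsds = []
        for seed in range(10):
            cfg = SyntheticRunConfig(seed=seed, area_cv=0.02,
                                     zero_intercept=True)
            areas = [make_sample_run(library, {"Rg1": 0.2}, cfg,
                                     label=f"t{h}").truth["Rg1"]["area"]
                     for h in (0, 2, 6, 12, 24, 48)]
            rsds.append(stability_series(areas))
        assert 0.5 < float(np.median(rsds)) < 4.0

    def test_single_timepoint_rejected(self):
        with pytest.raises(ValueError):
            stability_series([1.0])

    def test_zero_mean_rsd_undefined(self):
        with pytest.raises(ValueError):
            rsd([0.0, 0.0, 0.0])
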