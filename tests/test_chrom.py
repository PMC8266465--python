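"""XIC extraction, integration, noise estimation and RT-ratio matching."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ginsquant.chrom import (EmptyXICError, PeakMeasurement, PeakNotFoundError,
                             RelativeRT, XIC, estimate_noise, extract_xic,
                             extract_xic_scans, integrate_peak,
                             locate_peak_by_rtr, snr)
from ginsquant.synthetic import Channel, SyntheticRun, SyntheticRunConfig


def _run_with_channels(mzs):
    t = np.linspace(0.0, 1.0, 60)
    channels = [Channel(mz=mz, time=t, intensity=np.full_like(t, i + 1.0))
                for i, mz in enumerate(mzs)]
    return SyntheticRun(channels=channels, truth={},
                        config=SyntheticRunConfig(seed=0))


def _gaussian_xic(height=1.0, rt=5.0, sigma=0.05, hz=10.0, span=2.0,
                  baseline=0.0, noise_sd=0.0, seed=0):
    n = int(span * 60 * hz)
    t = np.linspace(rt - span / 2, rt + span / 2, n)
    y = height * np.exp(-0.5 * ((t - rt) / sigma) ** 2) + baseline
    if noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0, noise_sd, n)
    return XIC(target_mz=500.0, ppm_window=10.0, time=t, intensity=y)


class TestExtract:
    def test_finds_channel_within_tolerance(self):
        run = _run_with_channels([1107.5956, 945.5451])
        xic = extract_xic(run, 1107.60, 20.0)
        assert xic.intensity[0] == 1.0

    def test_no_channel_raises(self):
        run = _run_with_channels([945.5451])
        with pytest.raises(EmptyXICError):
            extract_xic(run, 500.0, 5.0)

    def test_nearest_of_two_close_channels_wins(self):
        # brute-force oracle: smallest ppm distance
        mzs = [783.49, 783.50]
        query = 783.4913
        run = _run_with_channels(mzs)
        expected = min(range(2), key=lambda i: abs(mzs[i] - query))
        xic = extract_xic(run, query, 20.0)
        assert xic.intensity[0] == expected + 1.0

    def test_scan_based_extraction_matches_channelised(self):
        rng = np.random.default_rng(0)
        times = np.linspace(0, 1, 30)
        scans = [{"rt_min": t,
                  "m/z array": np.array([400.0, 500.0, 600.0]),
                  "intensity array": np.array([1.0, 10.0 + i, 2.0])}
                 for i, t in enumerate(times)]
        xic = extract_xic_scans(scans, 500.0, 10.0)
        assert np.array_equal(xic.intensity, 10.0 + np.arange(30))


class TestIntegrate:
    def test_gaussian_area_closed_form(self):
        xic = _gaussian_xic(height=1.0, sigma=0.05)
        peak = integrate_peak(xic, (4.5, 5.5))
        assert peak.area == pytest.approx(0.05 * np.sqrt(2 * np.pi), rel=5e-3)
        assert peak.rt_apex == pytest.approx(5.0, abs=0.01)

    def test_flat_zero_trace(self):
        t = np.linspace(0, 1, 100)
        xic = XIC(500.0, 10.0, t, np.zeros_like(t))
        peak = integrate_peak(xic, (0.2, 0.8))
        assert peak.area == 0.0 and peak.snr == 0.0

    def test_rectangular_pulse_exact(self):
        dt = 0.01
        t = np.arange(0, 1, dt)
        y = np.where((t >= 0.4) & (t < 0.6), 3.0, 0.0)
        m = int(np.sum(y > 0))
        xic = XIC(500.0, 10.0, t, y)
        peak = integrate_peak(xic, (0.2, 0.8))
        assert peak.area == pytest.approx(3.0 * m * dt, rel=1e-12)

    @given(st.floats(min_value=0.01, max_value=100.0))
    def test_linearity_in_intensity(self, scale):
        base = _gaussian_xic(height=1.0)
        scaled = XIC(base.target_mz, base.ppm_window, base.time,
                     base.intensity * scale)
        p0 = integrate_peak(base, (4.5, 5.5))
        p1 = integrate_peak(scaled, (4.5, 5.5))
        assert p1.area == pytest.approx(scale * p0.area, rel=1e-9)
        assert p1.height == pytest.approx(scale * p0.height, rel=1e-9)

    def test_time_shift_invariance(self):
        base = _gaussian_xic()
        delta = 2.5
        shifted = XIC(base.target_mz, base.ppm_window, base.time + delta,
                      base.intensity)
        p0 = integrate_peak(base, (4.5, 5.5))
        p1 = integrate_peak(shifted, (4.5 + delta, 5.5 + delta))
        assert p1.rt_apex == pytest.approx(p0.rt_apex + delta, rel=1e-12)
        assert p1.area == pytest.approx(p0.area, rel=1e-12)

    def test_window_outside_span_rejected(self):
        xic = _gaussian_xic()
        with pytest.raises(ValueError):
            integrate_peak(xic, (100.0, 101.0))


class TestNoise:
    def test_pure_noise_estimate(self):
        rng = np.random.default_rng(2)
        t = np.linspace(0, 10, 1000)
        xic = XIC(500.0, 10.0, t, rng.normal(100.0, 5.0, t.size))
        assert estimate_noise(xic) == pytest.approx(5.0, rel=0.10)

    def test_all_zero_baseline(self):
        t = np.linspace(0, 1, 100)
        xic = XIC(500.0, 10.0, t, np.zeros_like(t))
        assert estimate_noise(xic) == 0.0

    def test_excluding_peak_recovers_peak_free_estimate(self):
        with_peak = _gaussian_xic(height=1000.0, noise_sd=5.0, seed=3)
        no_peak = _gaussian_xic(height=0.0, noise_sd=5.0, seed=3)
        est_excl = estimate_noise(with_peak, exclude=[(4.7, 5.3)])
        est_free = estimate_noise(no_peak)
        assert est_excl == pytest.approx(est_free, rel=0.10)

    def test_insufficient_points_rejected(self):
        xic = _gaussian_xic()
        span = (xic.time[0], xic.time[-1])
        with pytest.raises(ValueError):
            estimate_noise(xic, exclude=[span])


class TestSnr:
    def test_ratio(self):
        peak = PeakMeasurement("x", 1.0, 10.0, 30.0, 0.0, (0.9, 1.1))
        assert snr(peak, 10.0) == 3.0

    def test_zero_height(self):
        peak = PeakMeasurement("x", 1.0, 0.0, 0.0, 0.0, (0.9, 1.1))
        assert snr(peak, 10.0) == 0.0

    def test_zero_noise_undefined(self):
        peak = PeakMeasurement("x", 1.0, 1.0, 1.0, 0.0, (0.9, 1.1))
        with pytest.raises(ValueError):
            snr(peak, 0.0)


def _peak(rt, area=1.0):
    return PeakMeasurement("cand", rt, area, 1.0, 0.0, (rt - 0.1, rt + 0.1))


class TestRelativeRetention:
    def test_matches_reported_ratio(self):
        # Rg1 apex 1.46 vs Rb2 reference 7.09 -> ratio ~0.206, the reported
        # relative retention time rounds to 0.21
        ref = _peak(7.09)
        match = locate_peak_by_rtr([_peak(1.46), _peak(4.08)], ref,
                                   RelativeRT(0.21, "Rb2"), tol=0.05)
        assert match.rt_apex == 1.46

    def test_reference_matches_itself(self):
        ref = _peak(7.09)
        match = locate_peak_by_rtr([ref], ref, RelativeRT(1.0, "Rb2"),
                                   tol=0.01)
        assert match is ref

    def test_nearest_ratio_wins(self):
        # brute-force over candidate ratios
        ref = _peak(10.0)
        cands = [_peak(2.0), _peak(3.5)]
        expected = min(cands,
                       key=lambda p: abs(p.rt_apex / 10.0 - 0.21) / 0.21)
        match = locate_peak_by_rtr(cands, ref, RelativeRT(0.21, "r"),
                                   tol=0.05)
        assert match is expected

    def test_no_candidate_within_tolerance(self):
        ref = _peak(10.0)
        with pytest.raises(PeakNotFoundError):
            locate_peak_by_rtr([_peak(9.0)], ref, RelativeRT(0.21, "r"),
                               tol=0.05)

    def test_tie_broken_by_area(self):
        ref = _peak(10.0)
        lo, hi = _peak(2.1, area=1.0), _peak(2.1, area=5.0)
        # identical ratios: the larger peak wins deterministically
        match = locate_peak_by_rtr([lo, hi], ref, RelativeRT(0.21, "r"),
                                   tol=0.1)
        assert match is hi

    @given(st.floats(min_value=0.2, max_value=5.0))
    def test_ratio_invariant_under_time_rescaling(self, gamma):
        """Uniform flow-rate-like rescaling t -> gamma*t leaves the relative
        retention time unchanged."""
        ref = _peak(7.09 * gamma)
        cands = [_peak(1.46 * gamma), _peak(4.08 * gamma)]
        match = locate_peak_by_rtr(cands, ref, RelativeRT(0.206, "Rb2"),
                                   tol=0.05)
        assert match.rt_apex == pytest.approx(1.46 * gamma)
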