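"""Absorbance proxy, RMSE machinery, current and calibration metrics."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nanozyme2d.core import ScenarioConfig
from nanozyme2d.sensor import (
    SpectrumSet,
    absorbance_spectra,
    amperometric_current,
    calibrate_sigma_blank,
    calibration_metrics,
    cumulative_h2o2_consumed,
    rmse_spectra,
    sensitivity_sweep,
)


class TestAbsorbance:
    def test_zero_consumption_zero_spectrum(self):
        s = absorbance_spectra([0.0])
        assert np.all(s.absorbance == 0.0)

    def test_maximum_at_band_center(self):
        s = absorbance_spectra([0.03])
        k = np.argmax(s.absorbance[0])
        assert s.wavelengths[k] == pytest.approx(s.band_center, abs=2.0)

    def test_monotone_in_glucose_at_band_center(self, cfg):
        consumed = [cumulative_h2o2_consumed(cfg, c)
                    for c in (0.5, 5.0, 10.0)]
        s = absorbance_spectra(consumed, concentrations=[0.5, 5.0, 10.0])
        center = s.at_band_center()
        assert np.all(np.diff(center) > 0.0)


class TestRMSE:
    def _make(self, A):
        wl = np.linspace(500.0, 800.0, A.shape[1])
        return SpectrumSet(wavelengths=wl, absorbance=A,
                           concentrations=np.arange(A.shape[0]))

    def test_identical_is_zero(self):
        a = self._make(np.random.default_rng(0).random((3, 50)))
        assert rmse_spectra(a, a) == 0.0

    def test_constant_offset(self):
        rng = np.random.default_rng(1)
        A = rng.random((2, 40))
        assert rmse_spectra(self._make(A), self._make(A + 0.05)) == \
            pytest.approx(0.05, rel=1e-12)

    def test_against_loop_summed_oracle(self):
        rng = np.random.default_rng(2)
        A, B = rng.random((3, 30)), rng.random((3, 30))
        total = 0.0
        count = 0
        for i in range(3):
            for j in range(30):
                total += (A[i, j] - B[i, j]) ** 2
                count += 1
        assert rmse_spectra(self._make(A), self._make(B)) == pytest.approx(
            np.sqrt(total / count), abs=1e-12)

    @given(st.integers(0, 1000))
    def test_metric_properties(self, seed):
        rng = np.random.default_rng(seed)
        A, B = rng.random((2, 20)), rng.random((2, 20))
        d = rmse_spectra(self._make(A), self._make(B))
        assert d >= 0.0
        assert d == rmse_spectra(self._make(B), self._make(A))

    def test_grid_mismatch_rejected(self):
        a = self._make(np.zeros((1, 20)))
        b = SpectrumSet(wavelengths=np.linspace(400, 700, 20),
                        absorbance=np.zeros((1, 20)),
                        concentrations=np.zeros(1))
        with pytest.raises(ValueError):
            rmse_spectra(a, b)


class TestCurrent:
    def test_zero_flux_zero_current(self):
        assert amperometric_current(0.0) == 0.0

    def test_direct_product(self):
        i = amperometric_current(1e-6, n=2, F=96485.0,
                                 electrode_area=1e-4)
        assert i == pytest.approx(1.93e-5, rel=1e-3)

    def test_linear_in_area(self):
        i1 = amperometric_current(1e-6, electrode_area=1e-4)
        i2 = amperometric_current(1e-6, electrode_area=2e-4)
        assert i2 == pytest.approx(2.0 * i1, rel=1e-14)


class TestCalibrationMetrics:
    def test_ideal_linear_curve_lod_closed_form(self):
        C = np.linspace(0.01, 2.0, 12)
        S = 3.7e-5
        r = calibration_metrics(C, S * C, sigma_blank=1e-8)
        assert r.sensitivity == pytest.approx(S, rel=1e-12)
        assert r.LOD_uM == pytest.approx(3.0 * 1e-8 / S * 1e3, rel=1e-12)
        assert r.linear_range_upper_mM == C[-1]

    def test_pure_mm_deviation_at_km_over_19(self):
        Km, V = 2.5, 1.0
        C = np.geomspace(1e-4, 1.0, 400)   # dense, slope -> V/Km exactly
        J = V * C / (Km + C)
        r = calibration_metrics(C, J, sigma_blank=1e-6,
                                low_conc_max=1e-3)
        assert r.linear_range_upper_mM == pytest.approx(Km / 19.0, rel=1e-2)

    def test_lod_scales_with_noise_and_inverse_slope(self):
        C = np.linspace(0.01, 2.0, 12)
        r1 = calibration_metrics(C, 1.0 * C, sigma_blank=1e-6)
        r2 = calibration_metrics(C, 1.0 * C, sigma_blank=2e-6)
        r3 = calibration_metrics(C, 2.0 * C, sigma_blank=1e-6)
        assert r2.LOD_uM == pytest.approx(2.0 * r1.LOD_uM, rel=1e-12)
        assert r3.LOD_uM == pytest.approx(0.5 * r1.LOD_uM, rel=1e-12)

    def test_nonpositive_slope_rejected(self):
        C = np.linspace(0.01, 2.0, 12)
        with pytest.raises(ValueError, match="slope"):
            calibration_metrics(C, -C, sigma_blank=1e-6)

    def test_sigma_blank_calibration_round_trip(self):
        sigma = calibrate_sigma_blank(1.0, lod_uM=1.37)
        C = np.linspace(0.01, 2.0, 12)
        r = calibration_metrics(C, 1.0 * C, sigma_blank=sigma)
        assert r.LOD_uM == pytest.approx(1.37, rel=1e-12)


@pytest.fixture(scope="module")
def report(cfg, coarse_grid):
    return sensitivity_sweep(cfg, grid=coarse_grid)


class TestSensitivitySweep:
    def test_report_shape_and_no_errors(self, report):
        assert len(report) == 15
        assert (report["error"] == "").all()

    def test_uniform_surface_recovers_intrinsic_km(self, report, cfg):
        row = report[(report.parameter == "A_gamma")
                     & (report.variation_pct == -100.0)].iloc[0]
        assert row.Km_eff_mM == pytest.approx(cfg.kinetics.Km, rel=1e-6)

    def test_baseline_lod_anchor(self, report):
        base = report[(report.parameter == "A_gamma")
                      & (report.variation_pct == 0.0)].iloc[0]
        assert base.LOD_uM == pytest.approx(1.37, rel=1e-9)

    def test_higher_loading_lowers_lod(self, report):
        rows = report[report.parameter == "Gamma_mean"].set_index(
            "variation_pct")
        assert rows.loc[50.0, "LOD_uM"] < rows.loc[0.0, "LOD_uM"]
        assert rows.loc[-50.0, "LOD_uM"] > rows.loc[0.0, "LOD_uM"]

    def test_stronger_heterogeneity_raises_apparent_km(self, report):
        rows = report[report.parameter == "A_gamma"].set_index(
            "variation_pct")
        assert rows.loc[-100.0, "Km_eff_mM"] < rows.loc[0.0, "Km_eff_mM"] \
            < rows.loc[50.0, "Km_eff_mM"]
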