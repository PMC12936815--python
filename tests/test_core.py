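"""Rate laws, heterogeneity profile, calibration and validity criteria."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nanozyme2d.core import (
    InvalidParameterError,
    ScenarioConfig,
    SurfaceKinetics,
    TransportParams,
    calibrate_reference,
    dimensionless_groups,
    gamma_profile,
    god_production_flux,
    mm_surface_rate,
    preset_for,
    validity_report,
)


class TestGammaProfile:
    def test_uniform_limit(self):
        kin = SurfaceKinetics(A_gamma=0.0)
        x = np.linspace(0.0, 10e-6, 33)
        g = gamma_profile(x, kin, lambda_het=10e-6)
        assert np.allclose(g, kin.Gamma_mean)

    def test_peak_at_origin(self):
        kin = SurfaceKinetics(A_gamma=0.5, phase=0.0)
        g = gamma_profile(np.array([0.0]), kin, lambda_het=10e-6)
        assert g[0] == pytest.approx(1.5 * kin.Gamma_mean, rel=1e-14)

    def test_mean_preserved_over_full_period(self):
        kin = SurfaceKinetics(A_gamma=0.5, phase=0.3)
        lam = 10e-6
        x = np.linspace(0.0, lam, 4097)
        g = gamma_profile(x, kin, lambda_het=lam)
        mean = np.trapezoid(g, x) / lam
        assert mean == pytest.approx(kin.Gamma_mean, rel=1e-12)

    def test_amplitude_above_one_rejected(self):
        with pytest.raises(InvalidParameterError):
            SurfaceKinetics(A_gamma=1.2)

    @given(st.floats(0.0, 1.0), st.floats(0.0, 2 * np.pi))
    def test_nonnegative_everywhere(self, A, phase):
        kin = SurfaceKinetics(A_gamma=A, phase=phase)
        x = np.linspace(0.0, 20e-6, 257)
        assert np.all(gamma_profile(x, kin, lambda_het=7e-6) >= 0.0)


class TestMMSurfaceRate:
    def test_half_saturation(self):
        r = mm_surface_rate(2.5, 1.2e-9, 1.2e5, 2.5)
        assert r == pytest.approx(0.5 * 1.2e5 * 1.2e-9 * 1e4, rel=1e-14)

    def test_zero_and_three_km(self):
        assert mm_surface_rate(0.0, 1e-9, 1e5, 2.5) == 0.0
        r = mm_surface_rate(7.5, 1e-9, 1e5, 2.5)
        assert r == pytest.approx(0.75 * 1e5 * 1e-9 * 1e4, rel=1e-14)

    def test_negative_concentration_rejected(self):
        with pytest.raises(InvalidParameterError):
            mm_surface_rate(-0.1, 1e-9, 1e5, 2.5)

    @given(
        st.floats(1e-12, 1e-6), st.floats(1e2, 1e7), st.floats(0.1, 50.0)
    )
    def test_monotone_and_bounded(self, Gamma, Vmax, Km):
        C = np.geomspace(1e-4, 1e3, 64)
        r = mm_surface_rate(C, Gamma, Vmax, Km)
        assert np.all(np.diff(r) >= 0.0)
        assert np.all(r <= Vmax * Gamma * 1e4 * (1 + 1e-12))


class TestGODSource:
    def test_zero_and_linearity(self):
        assert god_production_flux(0.0, 0.015, 1e-4) == 0.0
        f1 = god_production_flux(1.0, 0.015, 1e-4)
        assert god_production_flux(2.0, 0.015, 1e-4) == pytest.approx(
            2.0 * f1, rel=1e-14)

    def test_direct_product(self):
        f = god_production_flux(1.7, 0.015, 1e-4)
        assert f == pytest.approx(2.55e-6, rel=1e-12)


class TestCalibration:
    def test_depletion_anchor_satisfied(self, ref, cfg):
        # plug the calibrated J_max back into the 1D flux balance
        tr = cfg.transport
        k_m = tr.D_glu / tr.H
        C_b, C_s = 10.0, 1.7
        lhs = k_m * (C_b - C_s)
        rhs = ref.J_max * C_s / (2.5 + C_s)
        assert lhs == pytest.approx(rhs, rel=1e-14)

    def test_damkohler_matches_quadratic_oracle(self, ref):
        # independent route: the steady surface value solves
        # C^2 + (Km(1+Da) - C_b) C - C_b Km = 0; the anchored root must be
        # 0.17 * 10 mM.
        Km, C_b, Da = 2.5, 10.0, ref.Da_glu
        roots = np.roots([1.0, Km * (1 + Da) - C_b, -C_b * Km])
        C_s = roots[roots > 0].min()
        assert C_s == pytest.approx(1.7, rel=1e-12)

    def test_h2o2_anchor_feasible(self, ref, cfg):
        # the GOD conversion length reproduces the H2O2 surface anchor in
        # the coupled 1D balance
        tr = cfg.transport
        a = 0.015 * ref.delta_enz
        C_gs = 10.0 / (1.0 + a * tr.H / tr.D_glu)
        P = a * C_gs
        C_ps = 0.5
        sink = ref.J_max * C_ps / (2.5 + C_ps) + tr.D_h2o2 * C_ps / tr.H
        assert P == pytest.approx(sink, rel=1e-12)


class TestDimensionlessGroups:
    def test_pi_example(self, cfg):
        kin = cfg.kinetics.__class__(lambda_het=200e-9)
        g = dimensionless_groups(cfg.replace(kinetics=kin))
        assert g.Pi == pytest.approx(4e-6, rel=1e-12)

    def test_preset_damkohler(self, cfg):
        g = dimensionless_groups(cfg)
        assert g.Da_glu == pytest.approx(8.202352941, rel=1e-9)
        assert g.Da_p == pytest.approx(
            g.Da_glu * cfg.transport.D_glu / cfg.transport.D_h2o2, rel=1e-12)

    def test_doubling_H_quarters_pi(self, cfg):
        kin = cfg.kinetics.__class__(lambda_het=1e-6)
        g1 = dimensionless_groups(cfg.replace(kinetics=kin))
        tr2 = TransportParams(H=2 * cfg.transport.H)
        g2 = dimensionless_groups(cfg.replace(transport=tr2, kinetics=kin))
        assert g2.Pi == pytest.approx(g1.Pi / 4.0, rel=1e-12)


class TestValidityReport:
    def test_typical_regime_valid(self, cfg):
        kin = SurfaceKinetics(lambda_het=200e-9)
        rep = validity_report(cfg.replace(kinetics=kin), d_pt=50e-9,
                              theta=0.2)
        assert rep.regime == "pseudo2D_valid"
        assert all(f["passed"] for f in rep.flags.values())

    def test_breakdown_at_large_wavelength(self, cfg):
        kin = SurfaceKinetics(lambda_het=0.15 * cfg.transport.H)
        rep = validity_report(cfg.replace(kinetics=kin), d_pt=50e-9,
                              theta=0.2)
        assert rep.regime == "breakdown"

    def test_low_coverage_flagged(self, cfg):
        rep = validity_report(cfg, d_pt=50e-9, theta=0.03)
        assert not rep.flags["theta_coverage"]["passed"]

    def test_default_wavelength_sits_at_breakdown_boundary(self, cfg):
        # lambda = L = 10 um with H = 100 um sits at lambda/H = 0.1
        rep = validity_report(cfg, d_pt=50e-9, theta=0.2)
        assert rep.regime == "breakdown"
        assert rep.lam_over_H == pytest.approx(0.1)


class TestConfigValidation:
    def test_negative_bulk_rejected(self):
        with pytest.raises(InvalidParameterError):
            ScenarioConfig(C_bulk_list=(-1.0,))

    def test_mode_selects_rate_law(self, cfg, ref):
        p_el = preset_for(cfg.replace(mode="electrochemical"), ref)
        assert p_el.Km_glu == cfg.kinetics.Km_el
        assert p_el.J_max_glu == pytest.approx(
            ref.J_max * cfg.kinetics.Vmax_el / cfg.kinetics.Vmax, rel=1e-14)

    def test_thin_layer_rejected(self):
        with pytest.raises(InvalidParameterError):
            TransportParams(H=1e-12)
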