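"""Pseudo-2D solver: limits, conservation, oracle and convergence."""

import dataclasses

import numpy as np
import pytest
from scipy.optimize import root

from nanozyme2d.core import heterogeneity_factor, mm_rate, preset_for
from nanozyme2d.grid import Grid2D, stretched_nodes
from nanozyme2d.kinetics import effective_surface_and_flux, time_to_90
from nanozyme2d.solve1d import default_t_eval, solve_steady_1d, \
    solve_transient_colorimetric_1d
from nanozyme2d.solve2d import (
    solve_colorimetric_steady_2d,
    solve_steady_2d,
    solve_transient_2d,
    solve_transient_colorimetric_2d,
)


def _grid(cfg, nx, ny, ratio):
    tr = cfg.transport
    return Grid2D(x=np.linspace(0.0, tr.L, nx + 1),
                  y=stretched_nodes(tr.H, ny, ratio))


class TestSteady:
    def test_uniform_limit_matches_1d_columns(self, cfg, preset,
                                              coarse_grid):
        cfg0 = cfg.replace(kinetics=dataclasses.replace(
            cfg.kinetics, A_gamma=0.0))
        s2 = solve_steady_2d(cfg0, 10.0, preset, coarse_grid)
        p1 = solve_steady_1d(cfg0, 10.0, preset, coarse_grid.grid1d)
        diff = np.abs(s2.C["Glu"] - p1.C["Glu"][:, None])
        assert np.max(diff) / 10.0 < 1e-8

    def test_global_conservation(self, cfg, preset, coarse_grid):
        for C_b in (0.1, 2.0, 10.0):
            s2 = solve_steady_2d(cfg, C_b, preset, coarse_grid)
            assert s2.diagnostics["conservation_rel"] < 1e-6

    def test_residual_tolerance_met(self, cfg, preset, coarse_grid):
        s2 = solve_steady_2d(cfg, 5.0, preset, coarse_grid)
        assert s2.diagnostics["residual_rel"] < 1e-10

    def test_heterogeneity_penalty_on_flux(self, cfg, preset, coarse_grid):
        cfg0 = cfg.replace(kinetics=dataclasses.replace(
            cfg.kinetics, A_gamma=0.0))
        for C_b in (0.05, 0.5, 2.0, 10.0):
            _, J_het = effective_surface_and_flux(
                solve_steady_2d(cfg, C_b, preset, coarse_grid))
            _, J_uni = effective_surface_and_flux(
                solve_steady_2d(cfg0, C_b, preset, coarse_grid))
            assert J_het <= J_uni * (1 + 1e-10)

    def test_flux_monotone_in_bulk_concentration(self, sweep_coarse):
        assert np.all(np.diff(sweep_coarse["J_eff_2d"].to_numpy()) > 0.0)

    def test_matches_brute_force_newton_on_coarse_grid(self, cfg):
        # independent oracle: the same box-scheme balance written with
        # explicit loops over all unknowns and handed to a dense root
        # finder, no structure shared with the solver.
        preset = preset_for(cfg)
        g = Grid2D(x=np.linspace(0.0, cfg.transport.L, 20),
                   y=stretched_nodes(cfg.transport.H, 19, 1.35))
        C_b = 10.0
        D = cfg.transport.D_glu
        het = heterogeneity_factor(g.x, cfg.kinetics, cfg.lambda_het)
        nx, ny = g.nx, g.ny
        dx, dy = g.dx, g.dy
        wx, wy = g.wx, g.wy

        def resid(vec):
            C = np.empty((ny, nx))
            C[:-1] = vec.reshape(ny - 1, nx)
            C[-1] = C_b
            r = np.zeros((ny - 1, nx))
            for i in range(ny - 1):
                for j in range(nx):
                    acc = 0.0
                    if i < ny - 1:
                        acc += D * (C[i + 1, j] - C[i, j]) / dy[i] * wx[j]
                    if i > 0:
                        acc -= D * (C[i, j] - C[i - 1, j]) / dy[i - 1] * wx[j]
                    else:
                        cs = C[0, j]
                        acc -= het[j] * mm_rate(
                            cs, preset.J_max_glu, preset.Km_glu) * wx[j]
                    if j < nx - 1:
                        acc += D * (C[i, j + 1] - C[i, j]) / dx[j] * wy[i]
                    if j > 0:
                        acc -= D * (C[i, j] - C[i, j - 1]) / dx[j - 1] * wy[i]
                    # normalise each balance by its dominant coefficient so
                    # the dense root finder sees O(1) relative residuals
                    scale = D * C_b * (
                        wx[j] / dy[i]
                        + (wx[j] / dy[i - 1] if i > 0 else 0.0)
                        + 2.0 * wy[i] / dx.min()
                    )
                    r[i, j] = acc / scale
            return r.ravel()

        start = np.repeat(
            solve_steady_1d(cfg, C_b, preset, g.grid1d).C["Glu"][:-1], nx)
        sol = root(resid, start, method="hybr", tol=1e-13)
        assert np.max(np.abs(resid(sol.x))) < 1e-11
        oracle = sol.x.reshape(ny - 1, nx)

        ours = solve_steady_2d(cfg, C_b, preset, g)
        # the binding check: our converged field satisfies the
        # independently coded residual to below 1e-9 (relative units)
        assert np.max(np.abs(resid(ours.C["Glu"][:-1].ravel()))) < 1e-9
        # field agreement is limited by the dense solver's termination
        assert np.max(np.abs(ours.C["Glu"][:-1] - oracle)) / C_b < 1e-7

    def test_second_order_convergence_of_effective_flux(self, cfg, preset):
        # nested refinement: overall geometric growth held fixed while the
        # cell count doubles, so the mapping is refined systematically
        J = []
        for nx, ny, ratio in ((16, 24, 1.05 ** 4), (32, 48, 1.05 ** 2),
                              (64, 96, 1.05)):
            s = solve_steady_2d(cfg, 10.0, preset, _grid(cfg, nx, ny, ratio))
            J.append(effective_surface_and_flux(s)[1])
        p = np.log2(abs(J[1] - J[0]) / abs(J[2] - J[1]))
        assert 1.6 < p < 2.4


class TestColorimetricSteady:
    def test_no_god_means_no_peroxide(self, cfg, preset, coarse_grid):
        s = solve_colorimetric_steady_2d(
            cfg, 10.0, dataclasses.replace(preset, k_god=0.0), coarse_grid)
        assert np.all(s.C["H2O2"] == 0.0)

    def test_uniform_limit_peak_regression(self, cfg, preset, coarse_grid):
        cfg0 = cfg.replace(kinetics=dataclasses.replace(
            cfg.kinetics, A_gamma=0.0))
        s = solve_colorimetric_steady_2d(cfg0, 10.0, preset, coarse_grid)
        assert np.max(s.C["H2O2"]) / 10.0 == pytest.approx(0.05, rel=1e-6)

    def test_heterogeneous_boundary_layer_h2o2_not_below_uniform(
            self, cfg, preset, coarse_grid):
        # concavity of the consumption law makes the laterally averaged
        # H2O2 level at the surface at least the uniform-surface one
        cfg0 = cfg.replace(kinetics=dataclasses.replace(
            cfg.kinetics, A_gamma=0.0))
        s_het = solve_colorimetric_steady_2d(cfg, 10.0, preset, coarse_grid)
        s_uni = solve_colorimetric_steady_2d(cfg0, 10.0, preset, coarse_grid)
        wx, L = coarse_grid.wx, coarse_grid.L
        mean_het = float(s_het.C_s["H2O2"] @ wx / L)
        mean_uni = float(s_uni.C_s["H2O2"] @ wx / L)
        assert mean_het >= mean_uni * (1 - 1e-10)


class TestTransient:
    def test_uniform_limit_matches_1d_series(self, cfg, preset):
        cfg0 = cfg.replace(kinetics=dataclasses.replace(
            cfg.kinetics, A_gamma=0.0))
        grid = _grid(cfg, 8, 48, 1.1)
        t_eval = default_t_eval(60.0, 40)
        tr2 = solve_transient_colorimetric_2d(
            cfg0, 10.0, preset, grid, t_eval, rtol=1e-9, atol=1e-11)
        tr1 = solve_transient_colorimetric_1d(
            cfg0, 10.0, preset, grid.grid1d, t_eval,
            rtol=1e-9, atol=1e-11)
        for sp, scale in (("Glu", 10.0), ("H2O2", 0.5)):
            d = np.max(np.abs(tr2.C_s_mean[sp] - tr1.C_s[sp]))
            assert d / scale < 1e-6

    def test_terminal_state_matches_steady(self, cfg, preset):
        grid = _grid(cfg, 16, 48, 1.1)
        tr = solve_transient_2d(cfg, 10.0, preset, grid,
                                default_t_eval(120.0, 50))
        diff = np.abs(tr.final["Glu"] - tr.steady.C["Glu"])
        assert np.max(diff) / 10.0 < 0.005

    def test_t90_grid_insensitive(self, cfg, preset):
        t90 = []
        for nx, ny, ratio in ((8, 32, 1.1 ** 2), (16, 64, 1.1)):
            grid = _grid(cfg, nx, ny, ratio)
            tr = solve_transient_colorimetric_2d(
                cfg, 10.0, preset, grid, default_t_eval(60.0, 400),
                rtol=1e-9, atol=1e-11)
            wx, L = grid.wx, grid.L
            steady = float(tr.steady.C_s["H2O2"] @ wx / L)
            t90.append(time_to_90(tr.t, tr.C_s_mean["H2O2"], steady))
        assert abs(t90[1] - t90[0]) / t90[1] < 0.02
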