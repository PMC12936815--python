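"""Uniform-surface one-dimensional reference model.

At steady state the bulk of the diffusion layer carries no reaction, so the
concentration profile is exactly linear in y and the whole problem reduces
to a single nonlinear flux balance at the surface,

    (D/H) (C_bulk - C_s) = R(C_s),

with R the active Michaelis-Menten law.  The balance has a unique root in
[0, C_bulk] by monotonicity; it is solved by damped Newton with a
guaranteed bisection (Brent) fallback.  Transient solutions use a
conservative finite-volume semi-discretisation on the stretched vertical
grid and a stiff implicit integrator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .core import (
    Preset,
    ScenarioConfig,
    mm_rate,
    mm_rate_deriv,
    preset_for,
)
from .grid import Grid1D, stretched_nodes

__all__ = [
    "Profile1D",
    "Transient1D",
    "default_grid1d",
    "solve_steady_1d",
    "solve_colorimetric_steady_1d",
    "solve_transient_1d",
    "solve_transient_colorimetric_1d",
    "surface_balance_root",
]


def default_grid1d(cfg: ScenarioConfig, ny: int = 160,
                   ratio: float = 1.05) -> Grid1D:
    return Grid1D(y=stretched_nodes(cfg.transport.H, ny, ratio))


@dataclass(frozen=True)
class Profile1D:
    """Steady vertical profiles with surface values and fluxes.

    ``C`` maps species tag ('Glu', 'H2O2') to nodal concentrations (mM);
    ``C_s`` and ``J`` hold the surface concentration (mM) and the surface
    flux magnitude (mol m^-2 s^-1) per species; ``C_bulk`` the top Dirichlet
    values.
    """

    y: np.ndarray
    C: dict = field(default_factory=dict)
    C_s: dict = field(default_factory=dict)
    J: dict = field(default_factory=dict)
    C_bulk: dict = field(default_factory=dict)


@dataclass(frozen=True)
class Transient1D:
    """Transient solution: surface time series plus profile snapshots."""

    t: np.ndarray
    y: np.ndarray
    C_s: dict            # species -> series of surface concentration
    J: dict              # species -> series of surface flux
    profiles: dict       # species -> array (n_nodes, n_times)
    steady: Profile1D


def surface_balance_root(f, df, lo: float, hi: float,
                         tol: float = 1e-13, maxiter: int = 60) -> float:
    """Root of a monotone scalar balance on [lo, hi].

    Damped Newton from the midpoint, with bracket maintenance; falls back
    to Brent's method if Newton stalls or leaves the bracket.  ``tol`` is
    relative to the bracket width.
    """
    flo, fhi = f(lo), f(hi)
    if flo == 0.0:
        return lo
    if fhi == 0.0:
        return hi
    if flo * fhi > 0:
        raise ValueError("surface balance not bracketed")
    a, b = lo, hi
    x = 0.5 * (a + b)
    scale = max(abs(hi - lo), 1e-300)
    for _ in range(maxiter):
        fx = f(x)
        if fx * flo <= 0:
            b = x
        else:
            a = x
        d = df(x)
        step = fx / d if d != 0 else np.inf
        x_new = x - step
        if not (a < x_new < b):
            x_new = 0.5 * (a + b)
        if abs(x_new - x) <= tol * scale:
            return x_new
        x = x_new
    # Newton did not meet the tolerance; Brent is guaranteed to.
    return brentq(f, a, b, xtol=tol * scale)


def _linear_profile(y: np.ndarray, C_s: float, C_top: float) -> np.ndarray:
    H = y[-1]
    return C_s + (C_top - C_s) * y / H


def solve_steady_1d(cfg: ScenarioConfig, C_bulk: float,
                    preset: Preset | None = None,
                    grid: Grid1D | None = None) -> Profile1D:
    """Steady uniform-surface model for the glucose-consuming mode."""
    if C_bulk <= 0:
        raise ValueError("C_bulk must be positive")
    if preset is None:
        preset = preset_for(cfg)
    if grid is None:
        grid = default_grid1d(cfg)
    D, H = cfg.transport.D_glu, cfg.transport.H
    k_m = D / H
    Jm, Km = preset.J_max_glu, preset.Km_glu

    def f(cs):
        return k_m * (C_bulk - cs) - mm_rate(cs, Jm, Km)

    def df(cs):
        return -k_m - mm_rate_deriv(cs, Jm, Km)

    C_s = C_bulk if Jm == 0.0 else surface_balance_root(f, df, 0.0, C_bulk)
    J = k_m * (C_bulk - C_s)
    return Profile1D(
        y=grid.y,
        C={"Glu": _linear_profile(grid.y, C_s, C_bulk)},
        C_s={"Glu": C_s},
        J={"Glu": J},
        C_bulk={"Glu": C_bulk},
    )


def solve_colorimetric_steady_1d(cfg: ScenarioConfig, C_bulk: float,
                                 preset: Preset | None = None,
                                 grid: Grid1D | None = None) -> Profile1D:
    """Steady coupled 1D model: GOD glucose sink and H2O2 chain.

    Glucose is consumed by the first-order GOD step (closed form); the
    produced H2O2 is partly consumed by the nanozyme (Michaelis-Menten) and
    partly lost by diffusion to the peroxide-free bulk (Dirichlet 0 at
    y = H).
    """
    if C_bulk <= 0:
        raise ValueError("C_bulk must be positive")
    if preset is None:
        preset = preset_for(cfg)
    if grid is None:
        grid = default_grid1d(cfg)
    tr = cfg.transport
    k_mg = tr.D_glu / tr.H
    k_mp = tr.D_h2o2 / tr.H
    a = preset.k_god
    C_gs = C_bulk / (1.0 + a / k_mg)
    P = a * C_gs                     # H2O2 production flux

    def f(cp):
        return P - mm_rate(cp, preset.J_max_p, preset.Km_p) - k_mp * cp

    def df(cp):
        return -mm_rate_deriv(cp, preset.J_max_p, preset.Km_p) - k_mp

    if P == 0.0:
        C_ps = 0.0
    else:
        hi = P / k_mp                # consumption only increases with cp
        C_ps = surface_balance_root(f, df, 0.0, hi)
    return Profile1D(
        y=grid.y,
        C={
            "Glu": _linear_profile(grid.y, C_gs, C_bulk),
            "H2O2": _linear_profile(grid.y, C_ps, 0.0),
        },
        C_s={"Glu": C_gs, "H2O2": C_ps},
        J={"Glu": a * C_gs, "H2O2": k_mp * C_ps},
        C_bulk={"Glu": C_bulk, "H2O2": 0.0},
    )


# ---------------------------------------------------------------------------
# transient (method of lines)
# ---------------------------------------------------------------------------

def _laplacian_1d(grid: Grid1D, D: float):
    """FV Laplacian for unknowns at nodes 0..n-2 (top node Dirichlet).

    Returns (A, b) with d(C)/dt = A @ C + b * C_top + surface terms/vol[0].
    """
    n = grid.n
    m = n - 1
    dy = grid.dy
    vol = grid.vol
    main = np.zeros(m)
    lower = np.zeros(m - 1)
    upper = np.zeros(m - 1)
    b = np.zeros(m)
    for i in range(m):
        if i + 1 <= m - 1:
            c = D / dy[i] / vol[i]
            main[i] -= c
            upper[i] = c
        else:                         # neighbour above is the Dirichlet node
            c = D / dy[i] / vol[i]
            main[i] -= c
            b[i] = c
        if i > 0:
            c = D / dy[i - 1] / vol[i]
            main[i] -= c
            lower[i - 1] = c
    A = sparse.diags([lower, main, upper], [-1, 0, 1], format="csc")
    return A, b


def default_t_eval(sim_time: float, n: int = 160) -> np.ndarray:
    """Log-spaced output times starting at t = 0."""
    return np.concatenate(
        ([0.0], np.geomspace(sim_time * 1e-4, sim_time, n))
    )


def _surface_flux_series(profiles: np.ndarray, y: np.ndarray,
                         D: float) -> np.ndarray:
    """One-sided second-order dC/dy at y = 0 for each column of snapshots."""
    h1 = y[1] - y[0]
    h2 = y[2] - y[1]
    a0 = -(2.0 * h1 + h2) / (h1 * (h1 + h2))
    a1 = (h1 + h2) / (h1 * h2)
    a2 = -h1 / (h2 * (h1 + h2))
    return D * (a0 * profiles[0] + a1 * profiles[1] + a2 * profiles[2])


def solve_transient_1d(cfg: ScenarioConfig, C_bulk_step: float,
                       preset: Preset | None = None,
                       grid: Grid1D | None = None,
                       t_eval: np.ndarray | None = None,
                       C_init: np.ndarray | None = None,
                       rtol: float = 1e-8, atol: float = 1e-10) -> Transient1D:
    """Transient single-species (glucose) model after a bulk step.

    Initial condition: uniform ``C_bulk_step`` (per the quiescent-reservoir
    protocol) unless ``C_init`` is supplied explicitly.
    """
    if preset is None:
        preset = preset_for(cfg)
    if grid is None:
        grid = default_grid1d(cfg)
    if t_eval is None:
        t_eval = default_t_eval(cfg.sim_time)
    D = cfg.transport.D_glu
    A, b = _laplacian_1d(grid, D)
    vol0 = grid.vol[0]
    Jm, Km = preset.J_max_glu, preset.Km_glu
    m = grid.n - 1
    bc = b * C_bulk_step

    def rhs(t, C):
        out = A @ C + bc
        out[0] -= mm_rate(max(C[0], 0.0), Jm, Km) / vol0
        return out

    def jac(t, C):
        J = A.copy().tolil()
        J[0, 0] -= mm_rate_deriv(max(C[0], 0.0), Jm, Km) / vol0
        return J.tocsc()

    C0 = np.full(m, C_bulk_step) if C_init is None else np.asarray(
        C_init, dtype=float)[:m]
    sol = solve_ivp(rhs, (0.0, float(t_eval[-1])), C0, method="BDF",
                    t_eval=t_eval, jac=jac, rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"transient integration failed: {sol.message}")
    profiles = np.vstack([sol.y, np.full((1, sol.t.size), C_bulk_step)])
    steady = solve_steady_1d(cfg, C_bulk_step, preset, grid)
    return Transient1D(
        t=sol.t, y=grid.y,
        C_s={"Glu": profiles[0]},
        J={"Glu": _surface_flux_series(profiles, grid.y, D)},
        profiles={"Glu": profiles},
        steady=steady,
    )


def solve_transient_colorimetric_1d(
    cfg: ScenarioConfig, C_bulk_step: float,
    preset: Preset | None = None,
    grid: Grid1D | None = None,
    t_eval: np.ndarray | None = None,
    rtol: float = 1e-8, atol: float = 1e-10,
) -> Transient1D:
    """Transient coupled 1D model (GOD source, nanozyme H2O2 consumption).

    Glucose starts uniform at the stepped bulk value; H2O2 starts at zero
    everywhere with a zero Dirichlet value at the top (the reservoir holds
    no peroxide before the assay).
    """
    if preset is None:
        preset = preset_for(cfg)
    if grid is None:
        grid = default_grid1d(cfg)
    if t_eval is None:
        t_eval = default_t_eval(cfg.sim_time)
    tr = cfg.transport
    Ag, bg = _laplacian_1d(grid, tr.D_glu)
    Ap, bp = _laplacian_1d(grid, tr.D_h2o2)
    vol0 = grid.vol[0]
    m = grid.n - 1
    a = preset.k_god
    Jm, Km = preset.J_max_p, preset.Km_p
    bcg = bg * C_bulk_step           # H2O2 top value is 0

    def rhs(t, s):
        Cg, Cp = s[:m], s[m:]
        out = np.empty(2 * m)
        out[:m] = Ag @ Cg + bcg
        out[m:] = Ap @ Cp
        prod = a * max(Cg[0], 0.0)
        out[0] -= prod / vol0
        out[m] += (prod - mm_rate(max(Cp[0], 0.0), Jm, Km)) / vol0
        return out

    J_pattern = sparse.block_diag([Ag, Ap]).tolil()

    def jac(t, s):
        J = J_pattern.copy()
        J[0, 0] -= a / vol0
        J[m, 0] += a / vol0
        J[m, m] -= mm_rate_deriv(max(s[m], 0.0), Jm, Km) / vol0
        return J.tocsc()

    s0 = np.concatenate([np.full(m, C_bulk_step), np.zeros(m)])
    sol = solve_ivp(rhs, (0.0, float(t_eval[-1])), s0, method="BDF",
                    t_eval=t_eval, jac=jac, rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"transient integration failed: {sol.message}")
    pg = np.vstack([sol.y[:m], np.full((1, sol.t.size), C_bulk_step)])
    pp = np.vstack([sol.y[m:], np.zeros((1, sol.t.size))])
    steady = solve_colorimetric_steady_1d(cfg, C_bulk_step, preset, grid)
    return Transient1D(
        t=sol.t, y=grid.y,
        C_s={"Glu": pg[0], "H2O2": pp[0]},
        J={"Glu": _surface_flux_series(pg, grid.y, tr.D_glu),
           "H2O2": _surface_flux_series(pp, grid.y, tr.D_h2o2)},
        profiles={"Glu": pg, "H2O2": pp},
        steady=steady,
    )
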