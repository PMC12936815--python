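"""System-level observables: lateral averaging, apparent kinetics, t90.

The apparent (effective) Michaelis-Menten parameters are obtained by
fitting the laterally averaged surface flux J_eff against the laterally
averaged surface concentration C_eff_s over a bulk-concentration sweep.
Fitting against the *surface* concentration (not the bulk) means the
uniform 1D model returns the intrinsic parameters exactly, which makes the
normalised 1D reference values equal to one by construction and isolates
the heterogeneity-induced penalty in the pseudo-2D fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .core import Preset, ScenarioConfig, preset_for
from .grid import Grid2D
from .solve1d import Profile1D, solve_steady_1d
from .solve2d import Steady2D, default_grid2d, solve_steady_2d

__all__ = [
    "AveragedProfile",
    "MichaelisMentenModel",
    "MichaelisMentenFit",
    "EffectiveKinetics",
    "x_average",
    "effective_surface_and_flux",
    "fit_effective_mm",
    "diffusion_layer_thickness",
    "time_to_90",
    "run_sweep",
    "compare_effective_kinetics",
]


@dataclass(frozen=True)
class AveragedProfile:
    """x-averaged vertical concentration profile."""

    y: np.ndarray
    C_bar: np.ndarray
    C_bulk: float

    @property
    def normalized(self) -> np.ndarray:
        return self.C_bar / self.C_bulk


def x_average(field: np.ndarray, grid: Grid2D,
              C_bulk: float) -> AveragedProfile:
    """Trapezoidal lateral mean per y-row; exact for x-constant fields."""
    field = np.asarray(field, dtype=float)
    if field.shape != (grid.ny, grid.nx):
        raise ValueError(
            f"field shape {field.shape} does not match grid "
            f"({grid.ny}, {grid.nx})"
        )
    C_bar = field @ grid.wx / grid.L
    return AveragedProfile(y=grid.y, C_bar=C_bar, C_bulk=C_bulk)


def averaged_profile(sol, species: str = "Glu") -> AveragedProfile:
    """AveragedProfile from a steady 1D or pseudo-2D solution."""
    if isinstance(sol, Steady2D):
        return x_average(sol.C[species], sol.grid, sol.C_bulk[species])
    if isinstance(sol, Profile1D):
        C_bulk = sol.C_bulk[species]
        return AveragedProfile(y=sol.y, C_bar=sol.C[species].copy(),
                               C_bulk=C_bulk)
    raise TypeError(f"unsupported solution type {type(sol)!r}")


def effective_surface_and_flux(sol, species: str = "Glu"
                               ) -> tuple[float, float]:
    """Laterally averaged surface concentration (mM) and flux
    (mol m^-2 s^-1)."""
    if isinstance(sol, Steady2D):
        wx, L = sol.grid.wx, sol.grid.L
        C_eff = float(sol.C_s[species] @ wx / L)
        J_eff = float(sol.J[species] @ wx / L)
        return C_eff, J_eff
    if isinstance(sol, Profile1D):
        return float(sol.C_s[species]), float(sol.J[species])
    raise TypeError(f"unsupported solution type {type(sol)!r}")


# ---------------------------------------------------------------------------
# apparent Michaelis-Menten fit
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MichaelisMentenFit:
    """Results of an apparent Michaelis-Menten fit.

    ``params`` is (Vmax, Km); ``bse`` the asymptotic standard errors from
    the curve-fit covariance (NaN when the covariance is singular, e.g. for
    an exact fit); ``resid_norm`` the Euclidean norm of the flux residuals.
    """

    Vmax: float
    Km: float
    bse: tuple
    cov: np.ndarray
    resid_norm: float
    n_obs: int
    C_s: np.ndarray = field(repr=False, default=None)
    J: np.ndarray = field(repr=False, default=None)

    @property
    def params(self) -> tuple:
        return (self.Vmax, self.Km)

    def predict(self, C):
        C = np.asarray(C, dtype=float)
        return self.Vmax * C / (self.Km + C)

    def summary(self) -> str:
        lines = [
            "Apparent Michaelis-Menten fit",
            "=" * 45,
            f"{'observations':<22}{self.n_obs:>20d}",
            f"{'Vmax (flux units)':<22}{self.Vmax:>20.6e}",
            f"{'  std err':<22}{self.bse[0]:>20.3e}",
            f"{'Km (mM)':<22}{self.Km:>20.6f}",
            f"{'  std err':<22}{self.bse[1]:>20.3e}",
            f"{'residual norm':<22}{self.resid_norm:>20.3e}",
        ]
        return "\n".join(lines)


class MichaelisMentenModel:
    """Nonlinear least-squares model J = Vmax * C / (Km + C).

    The independent variable is the effective *surface* concentration.
    The initial guess comes from a Lineweaver-Burk linearisation
    (1/J = 1/Vmax + (Km/Vmax)(1/C)), used only to seed the nonlinear fit.
    """

    def __init__(self, C_s, J):
        C_s = np.asarray(C_s, dtype=float)
        J = np.asarray(J, dtype=float)
        if C_s.size != J.size:
            raise ValueError("C_s and J must have the same length")
        if C_s.size < 5:
            raise ValueError("need at least 5 (C_s, J) pairs")
        pos = C_s > 0
        if C_s[pos].max() / C_s[pos].min() < 10.0:
            raise ValueError("C_s must span at least one decade")
        self.C_s, self.J = C_s, J

    def _initial_guess(self) -> tuple[float, float]:
        mask = (self.C_s > 0) & (self.J > 0)
        x, y = 1.0 / self.C_s[mask], 1.0 / self.J[mask]
        slope, intercept = np.polyfit(x, y, 1)
        if intercept > 0 and slope > 0:
            V = 1.0 / intercept
            K = slope * V
            if np.isfinite(V) and np.isfinite(K) and V > 0 and K > 0:
                return V, K
        return float(self.J.max()), float(np.median(self.C_s))

    def fit(self, p0: tuple[float, float] | None = None
            ) -> MichaelisMentenFit:
        if p0 is None:
            p0 = self._initial_guess()
        try:
            popt, pcov = curve_fit(
                lambda C, V, K: V * C / (K + C),
                self.C_s, self.J, p0=p0,
                bounds=([0.0, 0.0], [np.inf, np.inf]), maxfev=10000,
            )
        except RuntimeError as exc:
            raise RuntimeError(
                f"Michaelis-Menten fit did not converge (p0={p0})"
            ) from exc
        resid = self.J - popt[0] * self.C_s / (popt[1] + self.C_s)
        bse = tuple(np.sqrt(np.diag(pcov)))
        return MichaelisMentenFit(
            Vmax=float(popt[0]), Km=float(popt[1]), bse=bse, cov=pcov,
            resid_norm=float(np.linalg.norm(resid)), n_obs=self.C_s.size,
            C_s=self.C_s, J=self.J,
        )


def fit_effective_mm(pairs) -> MichaelisMentenFit:
    """Fit the effective MM form to (C_eff_s, J_eff) pairs."""
    arr = np.asarray(list(pairs), dtype=float)
    return MichaelisMentenModel(arr[:, 0], arr[:, 1]).fit()


# ---------------------------------------------------------------------------
# scalar observables
# ---------------------------------------------------------------------------

def diffusion_layer_thickness(profile: AveragedProfile,
                              threshold: float = 0.99
                              ) -> tuple[float, bool]:
    """Smallest y where C_bar/C_bulk reaches ``threshold`` (delta99).

    Linear interpolation between the bracketing nodes.  If the profile
    never reaches the threshold the layer spans the whole domain: returns
    (H, True) with the saturation flag set.
    """
    c = profile.normalized
    y = profile.y
    above = c >= threshold
    if not above.any():
        return float(y[-1]), True
    k = int(np.argmax(above))
    if k == 0:
        return 0.0, False
    y0, y1 = y[k - 1], y[k]
    c0, c1 = c[k - 1], c[k]
    frac = (threshold - c0) / (c1 - c0)
    return float(y0 + frac * (y1 - y0)), False


def time_to_90(t: np.ndarray, series: np.ndarray, steady_value: float,
               level: float = 0.9) -> float:
    """First crossing time of ``level`` * steady value (linear interp).

    For non-monotone series the first crossing is returned.  Raises if the
    series never reaches the level within the horizon.
    """
    t = np.asarray(t, dtype=float)
    s = np.asarray(series, dtype=float)
    target = level * steady_value
    above = s >= target
    if not above.any():
        raise ValueError(
            "series never reaches 90% of steady state within the horizon; "
            "increase sim_time"
        )
    k = int(np.argmax(above))
    if k == 0:
        return float(t[0])
    frac = (target - s[k - 1]) / (s[k] - s[k - 1])
    return float(t[k - 1] + frac * (t[k] - t[k - 1]))


# ---------------------------------------------------------------------------
# sweep pipeline
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EffectiveKinetics:
    """Apparent kinetics of the pseudo-2D model, normalised to 1D.

    The 1D fit recovers the intrinsic parameters, so its normalised values
    are exactly one; the ratios isolate the heterogeneity penalty.
    """

    fit_1d: MichaelisMentenFit
    fit_2d: MichaelisMentenFit
    sweep: pd.DataFrame
    R_sat_ratio: float       # J_eff_2d / J_eff_1d at the top of the sweep

    @property
    def Km_eff_1d(self) -> float:
        return self.fit_1d.Km

    @property
    def Km_eff_2d(self) -> float:
        return self.fit_2d.Km

    @property
    def Vmax_ratio(self) -> float:
        return self.fit_2d.Vmax / self.fit_1d.Vmax

    def summary(self) -> str:
        rows = [
            ("", "Km_eff (mM)", "Vmax_eff (rel)", "R_sat (rel)"),
            ("1D uniform", f"{self.fit_1d.Km:.3f}", "1.000", "1.000"),
            ("pseudo-2D", f"{self.fit_2d.Km:.3f}",
             f"{self.Vmax_ratio:.3f}", f"{self.R_sat_ratio:.3f}"),
        ]
        w = 16
        return "\n".join("".join(f"{c:<{w}}" for c in r) for r in rows)


def run_sweep(cfg: ScenarioConfig,
              preset: Preset | None = None,
              grid: Grid2D | None = None,
              C_bulk_list=None,
              solve_2d: bool = True) -> pd.DataFrame:
    """Steady 1D and pseudo-2D solves over the bulk-concentration sweep.

    Returns a tidy frame with one row per bulk concentration and columns
    C_bulk, C_eff_s_1d, J_eff_1d and (when ``solve_2d``) C_eff_s_2d,
    J_eff_2d.
    """
    if preset is None:
        preset = preset_for(cfg)
    if grid is None:
        grid = default_grid2d(cfg)
    if C_bulk_list is None:
        C_bulk_list = cfg.C_bulk_list
    rows = []
    for C_b in C_bulk_list:
        p1 = solve_steady_1d(cfg, C_b, preset, grid.grid1d)
        row = {
            "C_bulk": C_b,
            "C_eff_s_1d": p1.C_s["Glu"],
            "J_eff_1d": p1.J["Glu"],
        }
        if solve_2d:
            s2 = solve_steady_2d(cfg, C_b, preset, grid)
            c2, j2 = effective_surface_and_flux(s2)
            row["C_eff_s_2d"] = c2
            row["J_eff_2d"] = j2
        rows.append(row)
    return pd.DataFrame(rows)


def compare_effective_kinetics(sweep: pd.DataFrame) -> EffectiveKinetics:
    """Fit apparent MM parameters to the 1D and pseudo-2D sweep data."""
    fit1 = MichaelisMentenModel(sweep["C_eff_s_1d"].to_numpy(),
                                sweep["J_eff_1d"].to_numpy()).fit()
    fit2 = MichaelisMentenModel(sweep["C_eff_s_2d"].to_numpy(),
                                sweep["J_eff_2d"].to_numpy()).fit()
    top = sweep["C_bulk"].idxmax()
    ratio = float(sweep.loc[top, "J_eff_2d"] / sweep.loc[top, "J_eff_1d"])
    return EffectiveKinetics(fit_1d=fit1, fit_2d=fit2, sweep=sweep,
                             R_sat_ratio=ratio)
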