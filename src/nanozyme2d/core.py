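"""Physical parameters, surface rate laws and preset calibration.

Units used throughout the package
---------------------------------
* lengths in m, time in s, diffusivities in m^2 s^-1;
* concentrations in mM, which equals mol m^-3, so that a mass-transfer
  velocity ``D/H`` (m s^-1) times a concentration (mol m^-3) is directly an
  areal flux in mol m^-2 s^-1;
* areal fluxes and areal reaction rates in mol m^-2 s^-1;
* site densities in mol cm^-2 (the unit they are tabulated in).

The solvers never use the tabulated per-site turnover numbers directly:
the maximal areal rate ``J_max`` is fixed by a Damkohler-number calibration
(see :func:`calibrate_reference`), because the tabulated ``Vmax * Gamma``
product is orders of magnitude too large to be consistent with the mild
surface depletion the model is meant to reproduce.  The tabulated values are
retained as metadata and are used only for relative scaling in sensitivity
sweeps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "TransportParams",
    "SurfaceKinetics",
    "ScenarioConfig",
    "DimensionlessGroups",
    "ValidityReport",
    "ReferenceCalibration",
    "Preset",
    "gamma_profile",
    "mm_surface_rate",
    "god_production_flux",
    "calibrate_reference",
    "preset_for",
    "dimensionless_groups",
    "validity_report",
]

# Tabulated reference values (used for defaults and sensitivity scaling).
D_GLU_REF = 6.7e-10        # m^2 s^-1
D_H2O2_REF = 1.5e-9        # m^2 s^-1
H_REF = 100e-6             # m
L_REF = 10e-6              # m
KM_REF = 2.5               # mM
VMAX_REF = 1.2e5           # s^-1 per site (metadata)
GAMMA_REF = 1.2e-9         # mol cm^-2 (metadata)
KGOD_REF = 0.015           # s^-1
KM_EL_REF = 3.8            # mM
VMAX_EL_REF = 8.5e4        # s^-1 per site (metadata)

# Calibration anchors: surface glucose depletion C_s/C_bulk at 10 mM bulk,
# and the normalized near-surface H2O2 level of the uniform 1D model.
ANCHOR_C_BULK = 10.0       # mM
ANCHOR_DEPLETION = 0.17    # C_s / C_bulk
ANCHOR_H2O2_PEAK = 0.05    # C_p,s / C_bulk


class InvalidParameterError(ValueError):
    """A physical parameter is outside its admissible range."""


@dataclass(frozen=True)
class TransportParams:
    """Diffusive transport and geometry of the diffusion layer."""

    D_glu: float = D_GLU_REF
    D_h2o2: float = D_H2O2_REF
    H: float = H_REF
    L: float = L_REF

    def __post_init__(self) -> None:
        errs = []
        for name in ("D_glu", "D_h2o2", "H", "L"):
            if not getattr(self, name) > 0:
                errs.append(f"{name} must be strictly positive")
        if not errs and self.H < self.L / 1000.0:
            errs.append("H must be at least L/1000")
        if errs:
            raise InvalidParameterError("; ".join(errs))


@dataclass(frozen=True)
class SurfaceKinetics:
    """Surface reaction parameters.

    ``lambda_het`` defaults to the lateral domain length (one full cosine
    period across the domain) and ``phase`` to zero so that the site-density
    gradient vanishes at both lateral walls, consistent with the no-flux
    lateral boundaries.  ``delta_enz`` is the effective conversion length of
    the first-order glucose-oxidase source; ``None`` means "use the
    calibrated preset value".
    """

    Km: float = KM_REF                 # mM
    Vmax: float = VMAX_REF             # s^-1 per site (metadata)
    Gamma_mean: float = GAMMA_REF      # mol cm^-2
    A_gamma: float = 0.5               # fraction of mean
    lambda_het: float | None = None    # m; None -> L
    phase: float = 0.0                 # rad
    kGOD: float = KGOD_REF             # s^-1
    delta_enz: float | None = None     # m; None -> calibrated
    Km_el: float = KM_EL_REF           # mM
    Vmax_el: float = VMAX_EL_REF       # s^-1 per site (metadata)

    def __post_init__(self) -> None:
        errs = []
        if not self.Km > 0:
            errs.append("Km must be strictly positive")
        if not self.Km_el > 0:
            errs.append("Km_el must be strictly positive")
        if not 0.0 <= self.A_gamma <= 1.0:
            errs.append(
                "A_gamma must lie in [0, 1]: amplitudes above 1 imply a "
                "negative site density"
            )
        if self.Gamma_mean < 0:
            errs.append("Gamma_mean must be nonnegative")
        if self.lambda_het is not None and not self.lambda_het > 0:
            errs.append("lambda_het must be strictly positive")
        if self.kGOD < 0:
            errs.append("kGOD must be nonnegative")
        if self.Vmax <= 0 or self.Vmax_el <= 0:
            errs.append("Vmax and Vmax_el must be strictly positive")
        if errs:
            raise InvalidParameterError("; ".join(errs))


Mode = Literal["colorimetric", "electrochemical"]


def _default_sweep() -> tuple[float, ...]:
    """12-point log-spaced bulk-concentration sweep over 0.01-12 mM."""
    pts = np.logspace(math.log10(0.01), math.log10(12.0), 12)
    pts[0], pts[-1] = 0.01, 12.0
    return tuple(pts)


@dataclass(frozen=True)
class ScenarioConfig:
    """Complete description of a simulation scenario.

    ``E_op`` and ``T`` appear in no governing equation; they are carried as
    metadata only, for provenance.
    """

    transport: TransportParams = field(default_factory=TransportParams)
    kinetics: SurfaceKinetics = field(default_factory=SurfaceKinetics)
    mode: Mode = "colorimetric"
    C_bulk_list: tuple[float, ...] = field(default_factory=_default_sweep)
    sim_time: float = 300.0   # s
    E_op: float = 0.7         # V vs Ag/AgCl (metadata)
    T: float = 310.0          # K (metadata)
    seed: int = 0

    def __post_init__(self) -> None:
        errs = []
        if self.mode not in ("colorimetric", "electrochemical"):
            errs.append(f"unknown mode {self.mode!r}")
        if len(self.C_bulk_list) == 0:
            errs.append("C_bulk_list must be nonempty")
        for c in self.C_bulk_list:
            if not 0.0 < c <= 50.0:
                errs.append(f"bulk concentration {c} mM outside (0, 50]")
                break
        if not self.sim_time > 0:
            errs.append("sim_time must be strictly positive")
        if errs:
            raise InvalidParameterError("; ".join(errs))

    @property
    def lambda_het(self) -> float:
        """Heterogeneity wavelength, defaulting to the domain length."""
        lam = self.kinetics.lambda_het
        return self.transport.L if lam is None else lam

    def replace(self, **kw) -> "ScenarioConfig":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# local rate laws
# ---------------------------------------------------------------------------

def gamma_profile(x: np.ndarray, kin: SurfaceKinetics,
                  lambda_het: float | None = None) -> np.ndarray:
    """Sinusoidal lateral site-density profile (mol cm^-2).

    Gamma(x) = Gamma_mean * (1 + A_gamma * cos(2 pi x / lambda + phase)).
    The zero-mean cosine modulation preserves the mean loading over an
    integer number of periods.
    """
    if kin.A_gamma > 1.0:
        raise InvalidParameterError("A_gamma > 1 gives negative site density")
    lam = lambda_het if lambda_het is not None else kin.lambda_het
    if lam is None:
        raise ValueError("lambda_het not set; pass it explicitly")
    x = np.asarray(x, dtype=float)
    return kin.Gamma_mean * (
        1.0 + kin.A_gamma * np.cos(2.0 * np.pi * x / lam + kin.phase)
    )


def heterogeneity_factor(x: np.ndarray, kin: SurfaceKinetics,
                         lambda_het: float) -> np.ndarray:
    """Dimensionless modulation g(x) = Gamma(x)/Gamma_mean >= 0."""
    x = np.asarray(x, dtype=float)
    return 1.0 + kin.A_gamma * np.cos(
        2.0 * np.pi * x / lambda_het + kin.phase
    )


def mm_surface_rate(C_s, Gamma, Vmax: float, Km: float):
    """Michaelis-Menten areal rate (mol m^-2 s^-1) from per-site turnover.

    ``Gamma`` is in mol cm^-2; the factor 1e4 converts to mol m^-2.
    Saturates at ``Vmax * Gamma * 1e4``; half-saturation at ``C_s = Km``.
    """
    C_s = np.asarray(C_s, dtype=float)
    if np.any(C_s < 0):
        raise InvalidParameterError("surface concentration must be >= 0")
    return Vmax * np.asarray(Gamma) * 1.0e4 * C_s / (Km + C_s)


def god_production_flux(C_glu_s, kGOD: float, delta_enz: float):
    """First-order glucose-oxidase H2O2 source flux (mol m^-2 s^-1).

    ``kGOD`` (s^-1) alone does not have the units of a surface rate
    constant; multiplying by the effective conversion length ``delta_enz``
    (m) yields a conversion velocity kGOD*delta_enz (m s^-1) and hence a
    well-defined areal flux kGOD*delta_enz*C_glu_s.
    """
    C_glu_s = np.asarray(C_glu_s, dtype=float)
    if np.any(C_glu_s < 0) or kGOD < 0 or delta_enz < 0:
        raise InvalidParameterError("GOD source inputs must be nonnegative")
    return kGOD * delta_enz * C_glu_s


# ---------------------------------------------------------------------------
# preset calibration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReferenceCalibration:
    """Anchored reference quantities shared by all scenarios.

    ``J_max`` is the maximal areal Michaelis-Menten rate (mol m^-2 s^-1) at
    the reference loading, fixed so that the uniform 1D steady model gives
    C_s = ANCHOR_DEPLETION * C_bulk at C_bulk = ANCHOR_C_BULK.  ``delta_enz``
    is fixed so the same 1D model's steady surface H2O2 equals
    ANCHOR_H2O2_PEAK * C_bulk at the same bulk glucose level.
    """

    J_max: float        # mol m^-2 s^-1
    delta_enz: float    # m
    Da_glu: float       # J_max * H / (D_glu * Km), at reference transport


def calibrate_reference(
    depletion: float = ANCHOR_DEPLETION,
    C_bulk: float = ANCHOR_C_BULK,
    Km: float = KM_REF,
    peak: float = ANCHOR_H2O2_PEAK,
) -> ReferenceCalibration:
    """Closed-form anchor calibration of ``J_max`` and ``delta_enz``.

    Steady 1D flux balance (D/H)(C_b - C_s) = J_max C_s/(Km + C_s) solved
    for J_max at C_s = depletion * C_b gives

        J_max = (D/H) (C_b - C_s)(Km + C_s)/C_s,
        Da    = J_max H / (D Km) = (C_b - C_s)(Km + C_s)/(C_s Km).

    The GOD conversion length follows from requiring the steady 1D H2O2
    surface value C_p,s = peak * C_b: with a linear H2O2 profile (zero at the
    top), production P = J_max C_p,s/(Km + C_p,s) + D_p C_p,s / H must equal
    kGOD delta_enz C_g,s with C_g,s = C_b/(1 + kGOD delta_enz H/D_g), whence
    kGOD delta_enz = P / (C_b - P H / D_g).
    """
    k_m = D_GLU_REF / H_REF
    C_s = depletion * C_bulk
    J_max = k_m * (C_bulk - C_s) * (Km + C_s) / C_s
    Da = J_max * H_REF / (D_GLU_REF * Km)

    C_ps = peak * C_bulk
    P = J_max * C_ps / (Km + C_ps) + D_H2O2_REF * C_ps / H_REF
    denom = C_bulk - P * H_REF / D_GLU_REF
    if denom <= 0:
        raise InvalidParameterError(
            "H2O2 peak anchor infeasible: required production exceeds "
            "the diffusive glucose supply"
        )
    a = P / denom                       # kGOD * delta_enz, m s^-1
    delta_enz = a / KGOD_REF
    return ReferenceCalibration(J_max=J_max, delta_enz=delta_enz, Da_glu=Da)


@dataclass(frozen=True)
class Preset:
    """Scenario-specific rate-law constants derived from the calibration.

    ``J_max_glu`` already includes the relative scaling of site density and
    turnover with respect to the reference loading, so sensitivity sweeps on
    Gamma_mean or Vmax act multiplicatively on the areal rate, as they do
    physically.
    """

    J_max_glu: float     # maximal areal rate of the active glucose law
    Km_glu: float        # mM, Michaelis constant of the active glucose law
    J_max_p: float       # maximal areal rate of H2O2 consumption
    Km_p: float          # mM
    k_god: float         # conversion velocity kGOD*delta_enz, m s^-1
    Da_glu: float        # dimensionless
    Da_p: float          # dimensionless


def preset_for(cfg: ScenarioConfig,
               ref: ReferenceCalibration | None = None) -> Preset:
    """Build the calibrated rate-law preset for a scenario.

    In colorimetric mode the glucose-consuming law uses (Km, Vmax); in
    electrochemical mode it uses (Km_el, Vmax_el).  H2O2 consumption by the
    nanozyme always uses the colorimetric pair (one peroxidase step).
    """
    if ref is None:
        ref = calibrate_reference()
    kin = cfg.kinetics
    tr = cfg.transport
    loading = kin.Gamma_mean / GAMMA_REF
    if cfg.mode == "electrochemical":
        Km_glu = kin.Km_el
        J_max_glu = ref.J_max * loading * kin.Vmax_el / VMAX_REF
    else:
        Km_glu = kin.Km
        J_max_glu = ref.J_max * loading * kin.Vmax / VMAX_REF
    J_max_p = ref.J_max * loading * kin.Vmax / VMAX_REF
    delta = kin.delta_enz if kin.delta_enz is not None else ref.delta_enz
    k_god = kin.kGOD * delta
    Da_glu = J_max_glu * tr.H / (tr.D_glu * Km_glu)
    Da_p = J_max_p * tr.H / (tr.D_h2o2 * kin.Km)
    return Preset(
        J_max_glu=J_max_glu, Km_glu=Km_glu,
        J_max_p=J_max_p, Km_p=kin.Km,
        k_god=k_god, Da_glu=Da_glu, Da_p=Da_p,
    )


def mm_rate(C, J_max: float, Km: float):
    """Areal Michaelis-Menten rate J_max*C/(Km+C) for calibrated presets."""
    C = np.asarray(C, dtype=float)
    return J_max * C / (Km + C)


def mm_rate_deriv(C, J_max: float, Km: float):
    C = np.asarray(C, dtype=float)
    return J_max * Km / (Km + C) ** 2


# ---------------------------------------------------------------------------
# dimensionless groups and pseudo-2D validity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DimensionlessGroups:
    Da_glu: float
    Da_p: float
    Pi: float           # (lambda_het / H)^2
    het_index: float    # A_gamma
    lam_over_H: float


def dimensionless_groups(cfg: ScenarioConfig,
                         ref: ReferenceCalibration | None = None
                         ) -> DimensionlessGroups:
    """Damkohler numbers and the lateral-to-vertical diffusion ratio."""
    preset = preset_for(cfg, ref)
    lam = cfg.lambda_het
    H = cfg.transport.H
    return DimensionlessGroups(
        Da_glu=preset.Da_glu,
        Da_p=preset.Da_p,
        Pi=(lam / H) ** 2,
        het_index=cfg.kinetics.A_gamma,
        lam_over_H=lam / H,
    )


@dataclass(frozen=True)
class ValidityReport:
    Pi: float
    lam_over_H: float
    theta_coverage: float
    d_pt: float
    flags: dict
    regime: Literal["pseudo2D_valid", "marginal", "breakdown"]


def validity_report(cfg: ScenarioConfig, d_pt: float,
                    theta: float) -> ValidityReport:
    """Evaluate the scale-separation criteria of the pseudo-2D approximation.

    Criteria (with the encoded thresholds): lambda/H < 0.01 for rapid
    lateral equilibration, Pt coverage theta > 5% to avoid isolated
    micro-domains, Pi = (lambda/H)^2 < 0.01, and cluster size d_pt < H/100.
    The regime is 'breakdown' when lambda/H >= 0.1, 'marginal' when
    0.01 <= lambda/H < 0.1, and 'pseudo2D_valid' otherwise.
    """
    lam = cfg.lambda_het
    H = cfg.transport.H
    r = lam / H
    Pi = r * r
    flags = {
        "lam_over_H": {"value": r, "threshold": 0.01, "passed": r < 0.01},
        "theta_coverage": {"value": theta, "threshold": 0.05,
                           "passed": theta > 0.05},
        "Pi": {"value": Pi, "threshold": 0.01, "passed": Pi < 0.01},
        "d_pt_over_H": {"value": d_pt / H, "threshold": 0.01,
                        "passed": d_pt / H < 0.01},
    }
    if r >= 0.1:
        regime = "breakdown"
    elif r >= 0.01:
        regime = "marginal"
    else:
        regime = "pseudo2D_valid"
    return ValidityReport(Pi=Pi, lam_over_H=r, theta_coverage=theta,
                          d_pt=d_pt, flags=flags, regime=regime)
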