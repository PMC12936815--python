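"""Sensor-level readouts: colorimetric proxy, current, LOD, sensitivity.

The absorbance model is an explicit *proxy*: the chromogen chemistry (TMB
oxidation) is not modelled mechanistically; the cumulative H2O2 consumed by
the nanozyme over the incubation window is mapped linearly onto a single
Gaussian absorbance band at 652 nm.  It provides the plumbing needed for
spectra comparison and RMSE machinery, not a chemical prediction.

Calibration metrics follow standard analytical-chemistry conventions: the
limit of detection is 3 * sigma_blank / slope of the low-concentration
linear fit, and the upper end of the linear range is the smallest
concentration at which the response falls more than 5% below that line.
``sigma_blank`` has no counterpart in the transport model and is set once
(see :func:`calibrate_sigma_blank`); only relative LOD trends across the
sensitivity sweep are model predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd

from .core import ScenarioConfig, preset_for
from .kinetics import MichaelisMentenModel, run_sweep
from .solve1d import solve_colorimetric_steady_1d

__all__ = [
    "SpectrumSet",
    "SensorReadout",
    "FARADAY",
    "BAND_CENTER_NM",
    "DEFAULT_BAND_WIDTH_NM",
    "DEFAULT_ABS_SCALE",
    "DEFAULT_INCUBATION_S",
    "BASELINE_LOD_UM",
    "absorbance_spectra",
    "rmse_spectra",
    "amperometric_current",
    "cumulative_h2o2_consumed",
    "calibration_metrics",
    "calibrate_sigma_blank",
    "sensitivity_sweep",
]

FARADAY = 96485.33212                # C mol^-1
BAND_CENTER_NM = 652.0               # oxidised-TMB band
DEFAULT_BAND_WIDTH_NM = 40.0         # Gaussian sigma, nm
DEFAULT_ABS_SCALE = 18.0             # AU per mol m^-2 consumed; O(1) AU
DEFAULT_INCUBATION_S = 2400.0        # 40 min incubation window
BASELINE_LOD_UM = 1.37               # anchor for the sigma_blank preset


@dataclass(frozen=True)
class SpectrumSet:
    """Absorbance spectra, one row per glucose concentration."""

    wavelengths: np.ndarray           # nm
    absorbance: np.ndarray            # (n_conc, n_wl), AU
    concentrations: np.ndarray        # mM
    band_center: float = BAND_CENTER_NM
    band_width: float = DEFAULT_BAND_WIDTH_NM
    scale: float = DEFAULT_ABS_SCALE

    def at_band_center(self) -> np.ndarray:
        k = int(np.argmin(np.abs(self.wavelengths - self.band_center)))
        return self.absorbance[:, k]


def default_wavelengths() -> np.ndarray:
    return np.arange(500.0, 801.0, 2.0)


def absorbance_spectra(consumed, wavelengths=None,
                       concentrations=None,
                       band_center: float = BAND_CENTER_NM,
                       band_width: float = DEFAULT_BAND_WIDTH_NM,
                       scale: float = DEFAULT_ABS_SCALE) -> SpectrumSet:
    """Gaussian-band absorbance proxy from cumulative H2O2 consumption.

    A_i(lambda) = scale * consumed_i * exp(-(lambda-center)^2/(2 width^2)).
    """
    consumed = np.atleast_1d(np.asarray(consumed, dtype=float))
    if np.any(consumed < 0):
        raise ValueError("consumed amounts must be nonnegative")
    wl = default_wavelengths() if wavelengths is None else np.asarray(
        wavelengths, dtype=float)
    band = np.exp(-0.5 * ((wl - band_center) / band_width) ** 2)
    A = scale * consumed[:, None] * band[None, :]
    conc = (np.full(consumed.size, np.nan) if concentrations is None
            else np.asarray(concentrations, dtype=float))
    return SpectrumSet(wavelengths=wl, absorbance=A, concentrations=conc,
                       band_center=band_center, band_width=band_width,
                       scale=scale)


def rmse_spectra(sim: SpectrumSet, ref: SpectrumSet) -> float:
    """Root-mean-square absorbance difference over the shared grid."""
    if sim.wavelengths.shape != ref.wavelengths.shape or not np.allclose(
            sim.wavelengths, ref.wavelengths):
        raise ValueError("wavelength grids differ")
    if sim.absorbance.shape != ref.absorbance.shape:
        raise ValueError("spectrum sets have different shapes")
    d = sim.absorbance - ref.absorbance
    return float(np.sqrt(np.mean(d * d)))


def amperometric_current(J_eff_el: float, n: int = 2,
                         F: float = FARADAY,
                         electrode_area: float = 1e-4) -> float:
    """Faradaic current i = n F A J (A); area in m^2 (default 1 cm^2)."""
    if J_eff_el < 0 or electrode_area < 0:
        raise ValueError("flux and electrode area must be nonnegative")
    return n * F * electrode_area * J_eff_el


def cumulative_h2o2_consumed(cfg: ScenarioConfig, C_bulk: float,
                             t_inc: float = DEFAULT_INCUBATION_S,
                             preset=None) -> float:
    """Steady nanozyme H2O2 consumption rate times the incubation window.

    Uses the uniform 1D coupled model (closed form); units mol m^-2.
    """
    if preset is None:
        preset = preset_for(cfg)
    p = solve_colorimetric_steady_1d(cfg, C_bulk, preset)
    C_ps = p.C_s["H2O2"]
    rate = preset.J_max_p * C_ps / (preset.Km_p + C_ps)
    return float(rate * t_inc)


# ---------------------------------------------------------------------------
# calibration metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SensorReadout:
    """Calibration-curve metrics."""

    C_bulk: np.ndarray                # mM
    signal: np.ndarray                # flux or absorbance units
    sensitivity: float                # slope of the low-C linear fit
    LOD_uM: float
    linear_range_upper_mM: float
    sigma_blank: float

    def summary(self) -> str:
        return (
            f"sensitivity      {self.sensitivity:.6e} per mM\n"
            f"LOD              {self.LOD_uM:.3f} uM\n"
            f"linear range up  {self.linear_range_upper_mM:.3f} mM"
        )


def calibration_metrics(C_bulk, signal, sigma_blank: float,
                        low_conc_max: float | None = None,
                        deviation: float = 0.05) -> SensorReadout:
    """LOD and linear range from a calibration curve.

    The low-concentration slope is a through-origin least-squares fit over
    points with C <= ``low_conc_max`` (default: the lowest third of the
    sweep).  LOD = 3 sigma_blank / slope.  The linear range ends at the
    smallest concentration where the response deviates more than
    ``deviation`` (fractionally) below the linear fit, located by linear
    interpolation of the deviation between sweep points.
    """
    C = np.asarray(C_bulk, dtype=float)
    s = np.asarray(signal, dtype=float)
    if C.size < 8:
        raise ValueError("calibration curve needs at least 8 points")
    order = np.argsort(C)
    C, s = C[order], s[order]
    if low_conc_max is None:
        low_conc_max = C[max(2, C.size // 3)]
    mask = C <= low_conc_max
    if mask.sum() < 2:
        raise ValueError("too few points in the low-concentration regime")
    slope = float(np.sum(s[mask] * C[mask]) / np.sum(C[mask] ** 2))
    if slope <= 0:
        raise ValueError("non-positive calibration slope")
    lod_mM = 3.0 * sigma_blank / slope

    dev = 1.0 - s / (slope * C)
    beyond = dev > deviation
    if not beyond.any():
        upper = float(C[-1])
    else:
        k = int(np.argmax(beyond))
        if k == 0:
            upper = float(C[0])
        else:
            frac = (deviation - dev[k - 1]) / (dev[k] - dev[k - 1])
            upper = float(C[k - 1] + frac * (C[k] - C[k - 1]))
    return SensorReadout(
        C_bulk=C, signal=s, sensitivity=slope,
        LOD_uM=lod_mM * 1e3, linear_range_upper_mM=upper,
        sigma_blank=sigma_blank,
    )


def calibrate_sigma_blank(baseline_slope: float,
                          lod_uM: float = BASELINE_LOD_UM) -> float:
    """Blank noise level that pins the baseline LOD to its anchor value."""
    if baseline_slope <= 0:
        raise ValueError("baseline slope must be positive")
    return lod_uM * 1e-3 * baseline_slope / 3.0


# ---------------------------------------------------------------------------
# one-at-a-time sensitivity sweep
# ---------------------------------------------------------------------------

DEFAULT_VARIATIONS: tuple[tuple[str, float], ...] = (
    ("Gamma_mean", -50.0), ("Gamma_mean", 0.0), ("Gamma_mean", 50.0),
    ("A_gamma", -100.0), ("A_gamma", 0.0), ("A_gamma", 50.0),
    ("Km", -50.0), ("Km", 0.0), ("Km", 50.0),
    ("Vmax", -50.0), ("Vmax", 0.0), ("Vmax", 50.0),
    ("D_glu", -50.0), ("D_glu", 0.0), ("D_glu", 50.0),
)


def _vary_config(cfg: ScenarioConfig, param: str,
                 pct: float) -> ScenarioConfig:
    f = 1.0 + pct / 100.0
    kin, tr = cfg.kinetics, cfg.transport
    if param in ("Gamma_mean", "A_gamma", "Km", "Vmax"):
        kin = dc_replace(kin, **{param: getattr(kin, param) * f})
        return cfg.replace(kinetics=kin)
    if param == "D_glu":
        tr = dc_replace(tr, D_glu=tr.D_glu * f)
        return cfg.replace(transport=tr)
    raise ValueError(f"unknown sweep parameter {param!r}")


def sensitivity_sweep(cfg: ScenarioConfig,
                      variations=DEFAULT_VARIATIONS,
                      grid=None, C_bulk_list=None,
                      sigma_blank: float | None = None) -> pd.DataFrame:
    """One-at-a-time parameter sweep of the full pipeline.

    Each cell reruns the steady pseudo-2D sweep, refits the apparent MM
    parameters against the effective surface concentration, and recomputes
    LOD and linear range from the J_eff-vs-C_bulk calibration curve.
    ``sigma_blank`` defaults to the value calibrated on the unvaried
    baseline.  Solver failures are recorded per row instead of aborting
    the whole report.
    """
    base_sweep = run_sweep(cfg, grid=grid, C_bulk_list=C_bulk_list)
    base_metrics_input = (base_sweep["C_bulk"].to_numpy(),
                          base_sweep["J_eff_2d"].to_numpy())
    if sigma_blank is None:
        base_probe = calibration_metrics(*base_metrics_input,
                                         sigma_blank=0.0)
        sigma_blank = calibrate_sigma_blank(base_probe.sensitivity)

    rows = []
    for param, pct in variations:
        row = {"parameter": param, "variation_pct": pct}
        try:
            if pct == 0.0:
                sweep = base_sweep
            else:
                sweep = run_sweep(_vary_config(cfg, param, pct),
                                  grid=grid, C_bulk_list=C_bulk_list)
            fit = MichaelisMentenModel(sweep["C_eff_s_2d"].to_numpy(),
                                       sweep["J_eff_2d"].to_numpy()).fit()
            metrics = calibration_metrics(sweep["C_bulk"].to_numpy(),
                                          sweep["J_eff_2d"].to_numpy(),
                                          sigma_blank=sigma_blank)
            row.update({
                "Km_eff_mM": fit.Km,
                "Vmax_eff": fit.Vmax,
                "LOD_uM": metrics.LOD_uM,
                "linear_range_upper_mM": metrics.linear_range_upper_mM,
                "error": "",
            })
        except Exception as exc:      # partial report on per-cell failure
            row.update({"Km_eff_mM": np.nan, "Vmax_eff": np.nan,
                        "LOD_uM": np.nan, "linear_range_upper_mM": np.nan,
                        "error": str(exc)})
        rows.append(row)
    return pd.DataFrame(rows)
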