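"""Configuration files, result serialization and the run manifest.

Scenario files are plain YAML with two nested blocks (``transport``,
``kinetics``) and scalar top-level keys; every omitted field falls back to
the tabulated defaults, so an empty file is a valid scenario.  Validation
collects *all* violations (unknown keys, out-of-range values) into a
single error instead of stopping at the first.

All numeric CSV output is written at full double precision (shortest
round-trip repr), which makes regression comparisons bitwise-stable, and
every output file of a run is referenced in its JSON manifest.
"""

from __future__ import annotations

import dataclasses
import json
import time
from importlib import metadata as _metadata
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import (
    InvalidParameterError,
    ScenarioConfig,
    SurfaceKinetics,
    TransportParams,
    dimensionless_groups,
    preset_for,
    validity_report,
)
from .fixtures import generate_fixture_spectra
from .kinetics import (
    averaged_profile,
    compare_effective_kinetics,
    run_sweep,
    time_to_90,
)
from .sensor import SpectrumSet, sensitivity_sweep
from .solve2d import (
    Steady2D,
    default_grid2d,
    solve_colorimetric_steady_2d,
    solve_steady_2d,
    solve_transient_2d,
    solve_transient_colorimetric_2d,
)

__all__ = [
    "ValidationError",
    "load_scenario",
    "config_to_dict",
    "run_scenario",
    "write_spectra_csv",
    "read_spectra_csv",
]


class ValidationError(ValueError):
    """One or more configuration violations; the message lists them all."""


_SCALAR_KEYS = {"mode", "C_bulk_list", "sim_time", "E_op", "T", "seed"}


def _field_names(cls) -> set:
    return {f.name for f in dataclasses.fields(cls)}


def load_scenario(path) -> ScenarioConfig:
    """Load and fully validate a YAML scenario file.

    Missing fields take the tabulated defaults; an empty file yields the
    default scenario.  Unknown keys and out-of-range values are reported
    together in a single :class:`ValidationError`.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValidationError("scenario file must be a YAML mapping")
    errors: list[str] = []

    known_top = _SCALAR_KEYS | {"transport", "kinetics"}
    for key in raw:
        if key not in known_top:
            errors.append(f"unknown key {key!r}")

    def build(cls, block_name):
        block = raw.get(block_name, {}) or {}
        if not isinstance(block, dict):
            errors.append(f"{block_name!r} must be a mapping")
            return cls()
        names = _field_names(cls)
        for key in block:
            if key not in names:
                errors.append(f"unknown key {block_name}.{key!r}")
        kwargs = {k: v for k, v in block.items() if k in names}
        try:
            return cls(**kwargs)
        except InvalidParameterError as exc:
            errors.append(f"{block_name}: {exc}")
            return cls()

    transport = build(TransportParams, "transport")
    kinetics = build(SurfaceKinetics, "kinetics")
    kwargs = {k: raw[k] for k in _SCALAR_KEYS if k in raw}
    if "C_bulk_list" in kwargs:
        kwargs["C_bulk_list"] = tuple(float(c)
                                      for c in kwargs["C_bulk_list"])
    cfg = None
    try:
        cfg = ScenarioConfig(transport=transport, kinetics=kinetics,
                             **kwargs)
    except InvalidParameterError as exc:
        errors.append(str(exc))
    if errors:
        raise ValidationError("; ".join(errors))
    return cfg


def config_to_dict(cfg: ScenarioConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["C_bulk_list"] = list(d["C_bulk_list"])
    return d


# ---------------------------------------------------------------------------
# writers / readers
# ---------------------------------------------------------------------------

def write_field_csv(sol: Steady2D, path) -> None:
    """Long-format field snapshot: columns x, y, species, value."""
    grid = sol.grid
    xs, ys = np.meshgrid(grid.x, grid.y)
    frames = []
    for species, field in sol.C.items():
        frames.append(pd.DataFrame({
            "x": xs.ravel(), "y": ys.ravel(),
            "species": species, "value": field.ravel(),
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_profile_csv(profile, path) -> None:
    pd.DataFrame({"y": profile.y, "C_bar": profile.C_bar,
                  "C_norm": profile.normalized}).to_csv(path, index=False)


def write_spectra_csv(spectra: SpectrumSet, path) -> None:
    """Wavelength in the first column, one column per concentration."""
    df = pd.DataFrame({"wavelength_nm": spectra.wavelengths})
    for i, c in enumerate(spectra.concentrations):
        df[f"A_{c:g}mM"] = spectra.absorbance[i]
    df.to_csv(path, index=False)


def read_spectra_csv(path) -> SpectrumSet:
    df = pd.read_csv(path)
    wl = df["wavelength_nm"].to_numpy()
    cols = [c for c in df.columns if c.startswith("A_")]
    conc = np.array([float(c[2:-2]) for c in cols])
    A = np.vstack([df[c].to_numpy() for c in cols])
    return SpectrumSet(wavelengths=wl, absorbance=A, concentrations=conc)


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


# ---------------------------------------------------------------------------
# pipeline runner
# ---------------------------------------------------------------------------

def _version() -> str:
    try:
        return _metadata.version("nanozyme2d")
    except _metadata.PackageNotFoundError:
        return "unknown"


def run_scenario(cfg: ScenarioConfig, outdir, task: str = "fit",
                 nx: int = 64, ny: int = 160,
                 seed: int | None = None) -> dict:
    """Execute one pipeline task and write its outputs plus a manifest.

    Tasks: ``steady`` (sweep of steady solves + field snapshot),
    ``transient`` (glucose step response), ``colorimetric`` (coupled
    steady + transient, t90), ``fit`` (sweep + apparent-kinetics fits),
    ``sensitivity`` (one-at-a-time report), ``validate-regime``,
    ``fixtures`` (synthetic spectra).  Deterministic given config and seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = cfg.seed if seed is None else seed
    t_start = time.perf_counter()
    grid = default_grid2d(cfg, nx=nx, ny=ny)
    preset = preset_for(cfg)
    outputs: list[str] = []
    diagnostics: dict = {}

    def save_df(df: pd.DataFrame, name: str):
        df.to_csv(outdir / name, index=False)
        outputs.append(name)

    C_max = max(cfg.C_bulk_list)

    if task == "steady":
        sweep = run_sweep(cfg, preset, grid)
        save_df(sweep, "sweep.csv")
        sol = solve_steady_2d(cfg, C_max, preset, grid)
        write_field_csv(sol, outdir / "field.csv")
        outputs.append("field.csv")
        write_profile_csv(averaged_profile(sol), outdir / "xavg_profile.csv")
        outputs.append("xavg_profile.csv")
        diagnostics["steady"] = sol.diagnostics
    elif task == "transient":
        tr = solve_transient_2d(cfg, C_max, preset, grid)
        save_df(pd.DataFrame({"t": tr.t,
                              "C_s_mean": tr.C_s_mean["Glu"],
                              "J_mean": tr.J_mean["Glu"]}),
                "surface_series.csv")
        diagnostics["transient"] = tr.diagnostics
    elif task == "colorimetric":
        sol = solve_colorimetric_steady_2d(cfg, C_max, preset, grid)
        write_field_csv(sol, outdir / "field.csv")
        outputs.append("field.csv")
        tr = solve_transient_colorimetric_2d(cfg, C_max, preset, grid)
        save_df(pd.DataFrame({"t": tr.t,
                              "C_s_glu": tr.C_s_mean["Glu"],
                              "C_s_h2o2": tr.C_s_mean["H2O2"]}),
                "surface_series.csv")
        steady_p = float(sol.C_s["H2O2"] @ grid.wx / grid.L)
        diagnostics["t90_h2o2_s"] = time_to_90(
            tr.t, tr.C_s_mean["H2O2"], steady_p)
        diagnostics["steady"] = sol.diagnostics
    elif task == "fit":
        sweep = run_sweep(cfg, preset, grid)
        save_df(sweep, "sweep.csv")
        ek = compare_effective_kinetics(sweep)
        payload = {
            "Km_eff_1d_mM": ek.Km_eff_1d,
            "Km_eff_2d_mM": ek.Km_eff_2d,
            "Vmax_eff_ratio": ek.Vmax_ratio,
            "R_sat_ratio": ek.R_sat_ratio,
            "fit_1d": {"Vmax": ek.fit_1d.Vmax, "Km": ek.fit_1d.Km,
                       "resid_norm": ek.fit_1d.resid_norm},
            "fit_2d": {"Vmax": ek.fit_2d.Vmax, "Km": ek.fit_2d.Km,
                       "resid_norm": ek.fit_2d.resid_norm},
        }
        (outdir / "kinetics.json").write_text(
            json.dumps(payload, indent=2, default=_json_default))
        outputs.append("kinetics.json")
    elif task == "sensitivity":
        report = sensitivity_sweep(cfg, grid=grid)
        save_df(report, "sensitivity.csv")
    elif task == "validate-regime":
        groups = dimensionless_groups(cfg)
        rep = validity_report(cfg, d_pt=50e-9, theta=0.25)
        payload = {
            "Da_glu": groups.Da_glu, "Da_p": groups.Da_p,
            "Pi": rep.Pi, "lam_over_H": rep.lam_over_H,
            "regime": rep.regime, "flags": rep.flags,
        }
        (outdir / "validity.json").write_text(
            json.dumps(payload, indent=2, default=_json_default))
        outputs.append("validity.json")
    elif task == "fixtures":
        spectra = generate_fixture_spectra(
            seed, [c for c in cfg.C_bulk_list], cfg=cfg)
        write_spectra_csv(spectra, outdir / "fixture_spectra.csv")
        outputs.append("fixture_spectra.csv")
    else:
        raise ValueError(f"unknown task {task!r}")

    manifest = {
        "task": task,
        "config": config_to_dict(cfg),
        "version": _version(),
        "grid": {"nx": grid.nx, "ny": grid.ny,
                 "min_dy": float(np.min(grid.dy)),
                 "max_dy": float(np.max(grid.dy))},
        "preset": dataclasses.asdict(preset),
        "seed": seed,
        "outputs": outputs,
        "diagnostics": diagnostics,
        "wall_time_s": time.perf_counter() - t_start,
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=_json_default))
    return manifest
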