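"""Synthetic "experimental" absorbance spectra.

The experimental UV-vis spectra the colorimetric validation machinery is
meant to compare against are not published as numbers, so the comparison
plumbing is exercised with synthetic stand-ins: the package's own
absorbance proxy evaluated at the requested glucose concentrations plus
i.i.d. Gaussian noise.  These are synthetic fixtures, not data.
"""

from __future__ import annotations

import numpy as np

from .core import ScenarioConfig, preset_for
from .sensor import (
    SpectrumSet,
    absorbance_spectra,
    cumulative_h2o2_consumed,
    default_wavelengths,
)

__all__ = ["generate_fixture_spectra", "model_spectra"]


def model_spectra(cfg: ScenarioConfig, concentrations,
                  wavelengths=None, t_inc: float | None = None,
                  **band_kw) -> SpectrumSet:
    """Noise-free proxy spectra for a list of glucose concentrations."""
    preset = preset_for(cfg)
    kw = {} if t_inc is None else {"t_inc": t_inc}
    consumed = [cumulative_h2o2_consumed(cfg, c, preset=preset, **kw)
                for c in concentrations]
    wl = default_wavelengths() if wavelengths is None else wavelengths
    return absorbance_spectra(consumed, wavelengths=wl,
                              concentrations=concentrations, **band_kw)


def generate_fixture_spectra(seed: int, concentrations,
                             noise_sd: float = 0.02,
                             cfg: ScenarioConfig | None = None,
                             wavelengths=None) -> SpectrumSet:
    """Reproducible noisy spectra emulating an experimental dataset.

    With ``noise_sd = 0`` the fixtures equal the noise-free proxy exactly;
    otherwise i.i.d. Gaussian noise of the given standard deviation (AU) is
    added, clipped at zero from below (absorbance is nonnegative).
    """
    if cfg is None:
        cfg = ScenarioConfig()
    for c in concentrations:
        if not 0.01 * (1 - 1e-9) <= c <= 12.0 * (1 + 1e-9):
            raise ValueError(
                f"fixture concentration {c} mM outside the simulated "
                "0.01-12 mM range"
            )
    clean = model_spectra(cfg, concentrations, wavelengths=wavelengths)
    if noise_sd == 0.0:
        return clean
    rng = np.random.default_rng(seed)
    noisy = clean.absorbance + rng.normal(
        0.0, noise_sd, size=clean.absorbance.shape)
    return SpectrumSet(
        wavelengths=clean.wavelengths,
        absorbance=np.maximum(noisy, 0.0),
        concentrations=clean.concentrations,
        band_center=clean.band_center,
        band_width=clean.band_width,
        scale=clean.scale,
    )
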