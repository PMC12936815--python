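# nanozyme2d

Pseudo-two-dimensional reaction–diffusion modelling of heterogeneous
nanozyme glucose biosensors.

Glucose sensing with peroxidase-mimicking nanomaterials (here a
Ti₃C₂Tₓ MXene support carrying Pt clusters) is governed by the coupled
interplay of diffusive mass transport across a quiescent boundary layer and
saturable surface catalysis.  Real catalyst surfaces are laterally
non-uniform: Pt clusters form high-activity "hot spots" separated by
low-activity regions.  `nanozyme2d` resolves that heterogeneity with a
pseudo-2D model — two-dimensional Fickian diffusion of glucose and H₂O₂ in
the slab 0 ≤ y ≤ H above a laterally modulated catalytic boundary at
y = 0 — and extracts the system-level quantities a sensor designer cares
about: apparent kinetic parameters, diffusion-layer metrics, response
times, and calibration figures of merit (LOD, linear range).  It is aimed
at biosensor modellers and analytical chemists who want a transparent,
scriptable alternative to a commercial finite-element workflow.

## Model

In the solution slab each species obeys Fick's second law,
∂C/∂t = D ∇²C.  At the catalytic surface the diffusive flux balances the
heterogeneous Michaelis–Menten rate

    D ∂C/∂y |_{y=0} = J_max · g(x) · C_s / (K_m + C_s),
    g(x) = 1 + A_Γ cos(2π x / λ + φ),

with a Dirichlet reservoir at y = H, no-flux lateral walls, and — in the
colorimetric pathway — a first-order glucose-oxidase source of H₂O₂,
k_GOD·δ_enz·C_glu,s.  The maximal areal rate is fixed through a Damköhler
number Da = J_max H / (D K_m) calibrated so the uniform 1D model reproduces
a surface depletion of C_s = 0.17 C_bulk at 10 mM (Da ≈ 8.20); the GOD
conversion length δ_enz is calibrated so the 1D surface H₂O₂ level is
0.05 C_bulk at the same point.  Apparent kinetics are obtained by fitting
the laterally averaged flux J_eff against the laterally averaged surface
concentration C_s^eff over a 0.01–12 mM sweep,

    J_eff = V_max^eff · C_s^eff / (K_m^eff + C_s^eff),

so the uniform 1D model returns the intrinsic constants exactly and the
pseudo-2D fit isolates the heterogeneity-induced penalty.  See
`docs/methods.md` for the discretisation, calibration details and known
limitations.

## Worked example

```python
from nanozyme2d import (ScenarioConfig, run_sweep,
                        compare_effective_kinetics, dimensionless_groups)

cfg = ScenarioConfig()                   # tabulated preset parameters
g = dimensionless_groups(cfg)
print(f"Da_glu = {g.Da_glu:.3f}, Pi = {g.Pi:.3g}")

sweep = run_sweep(cfg)                   # 1D + pseudo-2D steady sweeps
ek = compare_effective_kinetics(sweep)
print(ek.summary())
```

prints

```
Da_glu = 8.202, Pi = 0.01
                Km_eff (mM)     Vmax_eff (rel)  R_sat (rel)
1D uniform      2.500           1.000           1.000
pseudo-2D       2.561           1.010           0.999
```

The 1D row returns the intrinsic Michaelis constant (2.5 mM) exactly — a
built-in consistency check of the fitting convention.  The pseudo-2D row
shows the heterogeneity penalty for the preset geometry (sinusoidal
modulation of amplitude 0.5 with wavelength λ = L = 10 µm under a
H = 100 µm diffusion layer): with λ/H = 0.1, lateral diffusion smooths the
surface perturbation within ~λ/2π of the boundary, so the apparent
constants shift by only a few percent.  Larger shifts require heterogeneity
wavelengths comparable to the layer thickness; `lambda_het` is an explicit
parameter for exactly that exploration.

A command-line interface mirrors the library:

```sh
nanozyme2d fit --outdir results/           # sweep + apparent kinetics
nanozyme2d sensitivity --outdir results/   # one-at-a-time parameter sweep
nanozyme2d validate-regime --outdir results/
```

Every run writes full-precision CSV/JSON outputs and a `manifest.json`
echoing the configuration, grid and convergence diagnostics.

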