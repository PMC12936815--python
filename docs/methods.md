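# Methods

## Model

`nanozyme2d` simulates dilute-species transport in the quiescent diffusion
layer above a flat catalytic sensor surface.  The domain is the rectangle
0 ≤ x ≤ L, 0 ≤ y ≤ H; each tracked species (glucose, hydrogen peroxide)
obeys Fick's second law with a constant diffusivity.  Convection and
electromigration are neglected: the intended operating conditions are
unstirred colorimetric assays and chronoamperometry in buffered
electrolyte, where diffusion dominates.  All reactions are confined to the
boundary y = 0:

* **Glucose-consuming mode.**  The surface consumes glucose at a
  Michaelis–Menten rate modulated laterally by the catalyst site density,
  R(x, C_s) = J_max·g(x)·C_s/(K_m + C_s), with
  g(x) = 1 + A_Γ cos(2πx/λ + φ).  The electrochemical variant uses the
  same form with its own pair (K_m,el, V_max,el).
* **Colorimetric pathway.**  Glucose is consumed by a laterally uniform
  first-order glucose-oxidase step with conversion velocity
  k_GOD·δ_enz (m s⁻¹); the same flux appears as an H₂O₂ source, and H₂O₂
  is consumed by the heterogeneous Michaelis–Menten law.  The chromogen
  chemistry itself is not modelled (see *Absorbance proxy*).

Boundary conditions: Dirichlet reservoir values at y = H (bulk glucose;
zero H₂O₂ — the reservoir holds no peroxide before the assay), no-flux
lateral walls.  The cosine phase defaults to zero and the wavelength to L,
so the modulation has ∂g/∂x = 0 at both walls, consistent with the no-flux
condition, and preserves the mean loading exactly.  Transients start from
a uniform glucose concentration at the stepped bulk value and zero H₂O₂.

### Why a calibrated Damköhler preset

The tabulated per-site turnover (V_max = 1.2×10⁵ s⁻¹) times the mean site
density (Γ = 1.2×10⁻⁹ mol cm⁻²) gives a maximal areal rate of
~1.2 mol m⁻² s⁻¹ — several thousand times too large to coexist with the
mild surface depletion the model is meant to describe (a surface at such a
rate would strip the boundary layer essentially to zero).  The package
therefore treats the surface-to-transport rate ratio, the Damköhler number
Da = J_max H/(D K_m), as the physically meaningful parameter and fixes it
by a single anchor: the uniform 1D steady model must give
C_s = 0.17·C_bulk at C_bulk = 10 mM.  The flux balance
(D/H)(C_b − C_s) = J_max C_s/(K_m + C_s) then yields, in closed form,

    J_max = (D/H)(C_b − C_s)(K_m + C_s)/C_s  ⇒  Da = 8.2024,
    J_max = 1.374×10⁻⁴ mol m⁻² s⁻¹.

The tabulated turnover and site density are retained as metadata and used
only *relatively*: sensitivity variations of Γ_mean or V_max scale J_max
multiplicatively, which is how they act physically.

Similarly, a bare first-order constant k_GOD (s⁻¹) cannot multiply a
concentration to give an areal flux; the package introduces an effective
conversion length δ_enz so that the GOD source is k_GOD·δ_enz·C_glu,s.
δ_enz is fixed by a second closed-form anchor — the uniform 1D steady
surface H₂O₂ equals 0.05·C_bulk at 10 mM bulk glucose — giving
δ_enz ≈ 3.71×10⁻⁴ m.  Both anchors are enforced as regression tests.

### Key parameters

| symbol | meaning | default | unit |
|---|---|---|---|
| D_glu, D_h2o2 | diffusivities | 6.7×10⁻¹⁰, 1.5×10⁻⁹ | m² s⁻¹ |
| H, L | layer thickness, lateral period | 100, 10 | µm |
| K_m (K_m,el) | Michaelis constant | 2.5 (3.8) | mM |
| A_Γ | heterogeneity amplitude | 0.5 | – |
| λ (lambda_het) | heterogeneity wavelength | L | m |
| k_GOD | GOD rate constant | 0.015 | s⁻¹ |
| δ_enz | GOD conversion length | calibrated (≈371 µm) | m |
| C_bulk sweep | bulk concentrations | 12 points, 0.01–12 (log) | mM |

Concentrations are handled in mM (≡ mol m⁻³), lengths in m, so D/H times a
concentration is directly an areal flux in mol m⁻² s⁻¹.  The operating
potential and temperature appear in no governing equation and are carried
as metadata only.

## Numerics

* **Discretisation.**  Conservative vertex-centred finite volumes on a
  tensor grid: uniform x (default 64 cells), geometrically stretched y
  (default 160 cells, growth 1.05), giving ≈100 cells within the first
  5 µm above the surface.  The operator is assembled as a Kronecker sum of
  1D operators; the nonlinear surface rate enters the bottom-row balances
  as a flux.  Because interior face fluxes telescope, the converged
  solution satisfies global conservation (top influx = integrated surface
  consumption) to the nonlinear-solver tolerance; this is checked on every
  steady solve.
* **Steady solves.**  Damped Newton with backtracking line search on the
  full residual, sparse LU for the linear systems, relative residual
  tolerance 10⁻¹⁰ (each row scaled by the magnitude of its linear part).
  The x-uniform 1D solution seeds the iteration; convergence takes 2–4
  steps at the preset.  Negative concentrations in a converged field raise
  an error rather than being clipped.  The 1D steady problem reduces to a
  single scalar flux balance (the bulk is source-free, so the profile is
  exactly linear); it is solved by damped Newton with a guaranteed Brent
  fallback, the root being unique by monotonicity.
* **Transients.**  Method of lines with the same spatial operator and BDF
  time stepping (relative tolerance 10⁻⁷, analytic sparse Jacobians,
  including the GOD coupling block in the two-species case).  Outputs are
  reported on a fixed log-spaced time grid.
* **Observables.**  Lateral means are trapezoidal (exact for x-constant
  fields); the surface flux uses a one-sided second-order stencil on the
  stretched grid.  δ99 is the smallest y where the x-averaged profile
  reaches 99% of bulk, linearly interpolated; t90 is the *first* crossing
  of 90% of the steady value, linearly interpolated — a deliberate
  tie-break, since the colorimetric step response overshoots (the uniform
  initial glucose field makes the early GOD production ≈1.8× its steady
  value, so surface H₂O₂ peaks ≈1.3× steady before relaxing).
* **Apparent kinetics.**  Nonlinear least squares of J_eff against the
  effective *surface* concentration, seeded by a Lineweaver–Burk
  linearisation.  Fitting against surface rather than bulk concentration
  makes the uniform 1D fit return the intrinsic parameters exactly, which
  pins the normalisation (all 1D-normalised quantities are 1 by
  construction) and makes the pseudo-2D shift a pure heterogeneity effect.

## Sensor metrics

LOD and linear range have no unique definition at the transport-model
level; the package adopts the standard analytical-chemistry conventions:
LOD = 3σ_blank/S with S the through-origin slope of the low-concentration
calibration fit, and the linear range ending where the response falls 5%
below that line.  σ_blank is not produced by the transport model; it is
set once so that the baseline preset yields LOD = 1.37 µM, after which all
sensitivity-sweep variations are genuine relative predictions.  The
absorbance model is an explicit proxy: cumulative H₂O₂ consumed over a
40-min incubation window maps linearly onto a Gaussian band at 652 nm.
The synthetic spectra generator adds seeded i.i.d. Gaussian noise to that
proxy; it exists to exercise the RMSE comparison plumbing and emulates
only the qualitative features of measured spectra (single chromophore
band, absorbance increasing with glucose), not instrument baselines,
band asymmetry or correlated noise — agreement with it demonstrates the
machinery, not spectroscopic accuracy.

## What the pseudo-2D model does — and does not — predict

Two exact structural identities of the steady model are worth stating
because they constrain every downstream observable:

1. The x-averaged steady field of a source-free diffusion layer is
   **exactly linear in y** (averaging the Laplace equation over x kills
   the lateral term at no-flux walls).  Hence δ99 of the averaged profile
   is essentially insensitive to heterogeneity: it can differ from the 1D
   value only through the surface value itself, by ≪1% at the preset.
2. The effective flux and effective surface concentration are rigidly
   linked, J_eff = (D/H)(C_bulk − C̄_s).  A heterogeneity that lowers the
   average flux necessarily *raises* the average surface concentration,
   and vice versa; they cannot both decrease.

At the preset geometry (λ = L = 10 µm, H = 100 µm, so λ/H = 0.1) a lateral
Fourier mode of the concentration field decays as e^(−2πy/λ), i.e. within
~1.6 µm of the surface, and the linearised surface perturbation amplitude
is A·J_max f(C_s)/(D·2π/λ + J_max f′(C_s)) ≈ 0.07 mM against C_s = 1.7 mM.
The heterogeneity penalty is therefore second order and small: the
apparent Michaelis constant shifts from 2.500 to ≈2.56 mM, the fitted
maximum rate and saturation flux change by ≈1%, and the penalty direction
(heterogeneous flux ≤ uniform flux at every bulk concentration, by the
concavity of the rate law) is confirmed numerically rather than assumed.
Order-unity shifts in the apparent constants require λ comparable to or
larger than H — outside the regime the validity calculator itself marks as
pseudo-2D-consistent, and reachable in the package by setting
`lambda_het` explicitly.  This tension is inherent to the model class:
strong heterogeneity effects and a well-separated pseudo-2D scale
hierarchy exclude each other.

## Problem sizes and tolerances used in the shipped analyses

The default analysis grid is 64×160 (stretched, growth 1.05) with a
12-point log-spaced sweep over 0.01–12 mM; a steady solve takes ~0.2 s and
the full acceptance pipeline ~20 s on one CPU.  The test suite uses
coarser grids (16–32 lateral cells, 48–96 vertical cells) for everything
except the convergence and acceptance checks; grid-convergence tests use
nested refinements that hold the overall geometric growth fixed while
doubling the cell count, and verify second-order convergence of the
effective flux and <2% grid sensitivity of t90.

## Known limitations

* The sinusoidal site-density profile is a first-order surrogate for
  stochastic Pt clustering; patchy or random fields with the same variance
  would produce equal or stronger local depletion.  Only the single-mode
  cosine is implemented.
* The GOD step is laterally uniform and first order; enzyme saturation and
  co-substrate (O₂) limitation are not modelled.
* No electrode kinetics (Butler–Volmer) or potential dependence: the
  electrochemical mode differs from the colorimetric one only through its
  Michaelis–Menten pair, and current is obtained from flux by i = nFA·J.
* TMB chemistry is reduced to the linear Gaussian-band proxy above.
* The transient protocol starts from a uniform glucose field; a
  reservoir-side step with an initially analyte-free layer would give
  slower, overshoot-free response curves.
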