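# Methods

## Physical model

The package solves the Pennes bioheat equation on a three-layer skin block
(epidermis, dermis, subcutaneous fat) or a homogeneous agar phantom.  Per
layer the model carries density ρ (kg/m³), specific heat c_p (J/kg/K),
conductivity k (W/m/K), blood perfusion rate ω_b (1/s) and the 850 nm
optical coefficients μ_a and μ_s′ (stored in 1/m; the conventional tables
quote 1/cm).  Defaults:

| layer | ρ | c_p | k | ω_b | μ_a (1/m) | μ_s′ (1/m) |
|---|---|---|---|---|---|---|
| epidermis | 1200 | 3950 | 0.24 | 0 | 90 | 3000 |
| dermis | 1090 | 3350 | 0.42 | 0.002 | 95 | 2000 |
| subcutaneous fat | 1210 | 2240 | 0.194 | 0.002 | 100 | 1800 |

Blood constants ρ_b = 1050 kg/m³, c_b = 3617 J/kg/K, arterial temperature
T_b = 310 K; metabolic heating Q_met = 368 W/m³ (0 for the phantom).  The
agar phantom uses ρ = 1050, c_p = 4219, k = 0.66, μ_a = 40 m⁻¹,
μ_s′ = 530 m⁻¹, with perfusion and metabolism off.

The LED source is the separable Gaussian/Beer–Lambert form
Q = μ_eff(z) · I(x, y) · e^(−τ(z)) with μ_eff = √(3 μ_a (μ_a + μ_s′)) and
I the 2-D Gaussian of total power P and standard deviation σ.  Because
∫ μ e^(−μz) dz = 1, the full radiometric power enters the tissue; no
Fresnel or diffuse-reflectance loss is modelled (the governing equations
are taken at face value, so P is power delivered into the tissue).  Two
optical-depth conventions are provided: `cumulative` (default),
τ(z) = ∫ μ_eff dz′, which is energy-continuous across layer interfaces, and
`local`, τ(z) = μ_eff(z)·z, the single-layer formula re-applied per layer
(kept for parity checks; it jumps at interfaces and over-deposits a few
per cent).  Lifting the LED off the skin affects only σ, via linear
interpolation between the two measured anchors (contact and 2000 µm);
outside that range σ is clamped with a warning.  No inverse-square factor
is applied — the gap's optical effect is beam broadening.

### Declared geometric assumptions

Layer thicknesses and domain extent are modelling inputs, not literature
constants: epidermis 0.1 mm, dermis to a 2.0 mm depth (so the two
interfaces sit at 0.1 and 2.0 mm, matching the 2 mm probe depth convention),
fat filling the rest of a 40 × 40 × 10 mm domain (50 mm wide for multi-LED
arrays so satellites at 10 mm stay clear of the insulated sides).  All are
configurable and echoed to the log.  Domain-size checks: widening to 60 mm
changes nothing measurable; deepening to 20 mm lowers the 300 mW peak by
&lt;0.1 K.  Multi-LED arrays place one LED at the origin and n−1 satellites
equally spaced on a 10 mm circle starting from +x; the angular arrangement
is a convention (only the centre-to-satellite distance is constrained).

## Discretization and solver

Structured cell-centred finite volumes: uniform lateral spacing, graded
vertical spacing (default 0.1 mm in the top 3 mm, 0.25 mm below; preview
grids grade 0.1 → 0.25 → 0.5 mm).  Lateral cell counts are kept odd so the
beam axis is a cell-centre column.  Face conductivities are harmonic means,
making interlayer flux continuous and the conduction operator symmetric
positive definite; the scheme conserves energy exactly up to the linear-
solver tolerance.

Time stepping is a θ-scheme (backward Euler θ=1, Crank–Nicolson θ=1/2
default, explicit θ=0 with a stability-limit check) written in increment
form: each implicit step solves (C/Δt + θ(K + P + B)) δ = r with a
matrix-free conjugate gradient, preconditioned by a symmetric tridiagonal
solve along z (the stiff direction).  Warm starts from the previous
increment keep iteration counts low near saturation.  Defaults: Δt = 0.25 s
(the shipped studies use 1.0 s after verifying the change is below
10⁻³ K), CG relative tolerance 1e-8 (1e-6 for the shipped studies, same
verification).

The mixed convective–radiative top boundary is folded into an effective
surface conductance U = 1/(1/(h + h_rad) + Δz₀/2k₀), which couples the
first cell centre to ambient through the half-cell conduction path — the
surface temperature is recovered from that flux balance rather than taken
as the first cell value.  The quartic radiation term uses
h_rad = ε σ_SB (T_s² + T∞²)(T_s + T∞), updated by Picard iteration each
implicit step to 10⁻⁴ K (typically 1–2 iterations; a frozen-coefficient
option exists).  An imposed-surface-flux setting supports analytic
benchmarks.  All temperatures are kelvin internally; every reported metric
is Celsius.

The phantom's equilibration temperature is not a property of the model and
must be supplied (default 25 °C = ambient, logged); likewise the phantom
validation power is a required input.

## Metrics and conventions

Isotherm volumes use the trilinear interpolant of the cell-centre lattice:
dual cells entirely above/below the threshold count fully/not at all and
straddling cells are subsampled (4³ default), which a dense-resampling
oracle reproduces to better than 2%.  Isotherm depth is the deepest
interpolated crossing on the beam-centre column (maximum over beam columns
for arrays).  Threshold-crossing times are linearly interpolated between
recorded samples (1 s cadence by default).

Percent drops are reported in two conventions side by side, because
published figures for this model family mix them: `_pct` columns divide by
the temperature rise above the 37 °C core baseline (physically meaningful
for heating; used for maximum-temperature drops), `_abs_pct` columns divide
by the absolute Celsius reading (used for the layer-interface drops, which
are conventionally quoted that way).  Multi-LED volume gains are reported
both as percent increase, 100·(V_n − V_1)/V_1, and as the ratio form
100·V_n/V_1.

## Synthetic measurement streams

Two generators stand in for laboratory data, so the fitting and
trace-comparison machinery is testable end to end:

* profiler scans — the closed-form irradiance sampled on a detector grid
  plus zero-mean Gaussian noise scaled by the peak (default 2%), clipped at
  zero.  They exercise the 2-D Gaussian least-squares fit (moment-based
  initialisation; scans narrower than one fitted σ are flagged
  ill-conditioned).
* thermocouple traces — a simulated probe series plus absolute Gaussian
  noise (default 0.3 °C, bracketing typical few-per-cent trial-to-trial
  variability), with independent replicates derived from consecutive seeds.

Both are deterministic per seed and carry their seeds in the output.  What
they deliberately do not emulate: detector saturation/warping, spectral
response, probe contact resistance, or drift — so passing the closure tests
demonstrates the statistical pipeline, not instrument physics.

## Validation

* Independent steady-state oracle: for a homogeneous perfused half-space
  under the Gaussian Beer–Lambert source with a linear Robin surface, the
  on-axis profile is computed by a Hankel-transform solution (exact
  two-exponential profile per radial mode) and matched by the solver to
  about 1% — this is the deepest cross-check, exercising conduction,
  perfusion, source and boundary together.
* Closed forms: the insulated uniform-perfusion ODE limit (matched to
  &lt;10⁻³ K) and 1-D constant-flux erfc conduction (matched to &lt;1%).
* Structure: exact equilibrium preservation, per-step energy balance to
  0.1%, explicit/implicit cross-scheme agreement, a maximum principle, and
  the 0.5% grid-refinement convergence criterion.

## Problem sizes of the shipped studies

The pre-built studies and the acceptance script run on coarsened grids
chosen as the package's standard reproduction configuration: sweeps on a
41×41×29 grid (1 mm lateral), single-run quantities on 81×81×29 (0.5 mm
lateral), multi-LED on 51×51×29 over a 50 mm footprint, all with Δt = 1 s.
Refining the lateral grid 2× or the vertical grid 2× moves the 300 mW peak
temperature by &lt;0.05 K, well inside the 0.5% convergence criterion.

## Known limitations

* Constant properties: no temperature-dependent conductivity or perfusion,
  no damage (Arrhenius/CEM43) feedback, no evaporation.
* The optical model is the diffusion-approximation Beer–Lambert form, which
  deposits all power along straight columns; it ignores lateral photon
  diffusion and the diffuse reflectance escaping the surface.  Fluence
  build-up near the surface of a highly scattering medium is likewise not
  represented.
* Cross-solver reproduction: ratio-type quantities (percent drops, relative
  volume gains) are robust, but absolute peak temperatures and isotherm
  depths inherit every unstated geometric and beam-calibration choice of a
  reference implementation.  Comparisons against values produced by other
  codes should be read with a 5–10% (or more, for threshold-derived
  quantities) cross-solver band in mind; this package's own convergence and
  oracle tests bound its internal numerical error far tighter.
* The insulated bottom/sides are faithful to the stated boundary conditions
  but mean very long heating of large domains will not reach a true
  semi-infinite steady state.
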