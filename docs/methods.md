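# Methods

`thermosar` models the thermal safety question posed by gradient-based
(dielectrophoretic) pulsed electromagnetic stimulation of a fractured
tibia stabilized with a metallic implant: how much does the conductive
implant heat under a sub-millitesla kHz drive, how is that heating
quantified from surface infrared measurements, and how far can the
unobservable internal temperature exceed the observed surface rise?

## Field model

The applicator is a conductor wound uniformly on a conical frustum.
With apex at the origin and axis along +z, the winding is
`r(s) = (s sin a cos ks, s sin a sin ks, s cos a)` with slant coordinate
`s ∈ [s1, s2]`, half-angle `a` and winding rate `k = 2πN/L`, `L = s2−s1`.
The azimuthal phase is taken as `k·s` (absolute slant coordinate), not
`k·(s−s1)`; the two differ only by a rigid rotation of the winding.

On the symmetry axis, Biot–Savart reduces to one scalar integral per
component with the closed integrands implemented in
`field.integrand_terms`; these equal the components of `dl × R`
(verified symbolically and, in the tests, against an explicit
tangent-cross-displacement oracle to ~1e-11 relative).  The integrals
have no closed form and are evaluated by adaptive quadrature
(`scipy.integrate.quad`, relative tolerance 1e-10, subinterval limit
scaled with the turn count because the integrand oscillates once per
turn; absolute floor 1e-13 for the symmetry-suppressed transverse
components).

Off the axis there is no comparable reduction, so `segment_field`
discretizes the winding into straight segments (default 200 per turn)
and sums midpoint-rule contributions; the same routine serves as the
independent on-axis oracle.  The midpoint error falls quadratically in
the segment length (≈(kΔs)²/24 relative), which sets the segment counts
used in the convergence and oracle tests.  Grid nodes within a guard
distance (2× the lattice spacing) of the winding are masked as NaN and
flagged rather than extrapolated.

Field non-uniformity — the quantity that drives dielectrophoretic
forces — is reported as `∇|B|²` on the lattice (central differences
inside, one-sided at boundaries).  This is a geometric surrogate: the
dielectrophoretic force proper scales with `∇|E|²`, and no off-axis
induced-field reconstruction is attempted.

**Fixture geometry.** Only the turn count (40), wire gauge and drive
(0.75 A RMS, 10 kHz, 50% duty) of the fabricated coil are public; the
half-angle and slant bounds are not.  The package ships a documented
fixture (`DEFAULT_COIL`: 45°, 2–12 cm, 40 turns) and labels every
geometry-dependent magnitude fixture-dependent.  With this fixture the
interior region of interest carries ~0.25–0.33 mT at 0.75 A — the right
order for inductive bone stimulators, but not a reproduction of any
published range.

## Excitation

PWM square drives are described by repetition rate, duty `D` and RMS
current; an ideal unipolar square has peak `I_rms/√D` (bipolar: peak =
RMS).  The switching stage is reduced to an RL step response
`i(t) = (V/R)(1 − e^{−tR/L})`; transistor saturation, flyback clamping
and wire parasitics are out of scope.

## Bioheat model

Heat transport follows the Pennes equation
`ρc ∂T/∂t = ∇·k∇T + ρ_b c_b ω_b (T_b − T) + Q_met + Q_ext` with the
electromagnetic source coupled through `Q_ext = ρ·SAR`,
`SAR = σE²_rms/ρ`.  For the non-perfused phantom the perfusion and
metabolic terms vanish.  Two perfusion parameterizations are accepted —
the exchange rate `ω_b` (1/s) or a volumetric mass perfusion
(kg·m⁻³·s⁻¹, the form in which cortical-bone values are usually cited);
they are converted internally via the blood density.

The 1-D solver uses a conservative finite-volume discretization on a
slab half-thickness (symmetry plane at x = 0) or a solid cylinder
(axis at r = 0, handled naturally by the face-area weighting), with
insulated, fixed-temperature or convective outer boundaries.  Backward
Euler (sparse LU) is the default and is unconditionally stable; forward
Euler is available and refuses steps beyond its Gershgorin stability
bound, reporting the maximum stable step.  For insulated domains the
per-step global energy balance is tracked and reported
(`energy_residual`); the FV construction keeps it at solver precision.
The standard central scheme is exact for the quadratic steady profile of
a uniformly heated slab, so the steady center-surface difference matches
`qL²/2k` essentially to machine precision at any resolution.

The lumped-capacitance limit `mc dT/dt = P_abs − hA·ΔT` is solved in
closed form for constant power (and via `solve_ivp` for time-varying
power).  Eddy-current implant heating uses the quasi-static
cylinder-in-axial-field model: induced azimuthal field `E = −(r/2)dB/dt`,
cross-section-averaged loss `σa²⟨(dB/dt)²⟩/8`.  Because an ideal square
wave has unbounded `dB/dt`, the drive must be band-limited: either a
trapezoid with finite rise time (default 1% of the period) or an
odd-harmonic truncation (default 15 harmonics); the two routes agree to
<0.5% on matched band-limited waveforms.  The skin depth at the
fundamental is checked against the radius; results outside the
quasi-static regime are flagged (`quasi_static_ok=False`), since flux
exclusion then makes the model an underestimate.

Material defaults: resin (ρ=1150 kg/m³, c=1300 J/(kg·K),
k=0.25 W/(m·K), σ=1e-8 S/m) and implant conductivity (1.4e6 S/m, μr=1)
are the published phantom/implant values; the steel density
(7900 kg/m³), heat capacity (500 J/(kg·K)) and thermal conductivity
(15 W/(m·K)) are representative austenitic figures chosen once, since
only σ and μr of the implant are on record.

## SAR_eff estimation

In the early-time lumped regime the absorbed power per unit mass follows
from the initial slope: `SAR_eff = c·dT/dt`.  The slope is an ordinary
least-squares fit over a configurable window, defaulting to the first
20 minutes (within which volumetric deposition still dominates
conduction and boundary loss); a two-point mode reproduces simple
rise-over-run arithmetic such as 0.4 K / 90 s = 4.44e-3 K/s.  The
estimate is exactly bilinear in slope and capacity, so heat-capacity
uncertainty propagates as an identical relative band (metal 450–550
J/(kg·K) → ±10%; resin 1200–1500 → ≈15%).  Negative slopes are returned
flagged as cooling rather than rejected.  Values are reported raw plus a
two-significant-figure display form.

A reporting ambiguity is preserved deliberately: the published implant
arithmetic pairs a 0.4 K rise with a 4.44e-3 K/s slope, which implies a
90 s interval although the surrounding text says "first three minutes";
the slope is treated as authoritative.  Likewise the published resin
figure (≈0.8 W/kg) is not exactly recoverable from its own inputs —
c=1300 with 0.05 K over 90 s gives 0.72 W/kg — so the package computes
and reports 0.72 rather than silently reconciling.

Thermal stabilization is declared at the earliest time from which every
native-sampling forward-difference rate within a continuous 600 s window
satisfies `|dT/dt| < 1e-4 K/s` (strict inequality; a rate exactly at the
threshold does not qualify).  On the published implant means this yields
1200 s.

**Peak-to-surface bound.** For uniform volumetric heating `ρ·SAR_eff` in
a wall of half-thickness `L_h`, the steady slab solution bounds the
internal excess: `ΔT_max − ΔT_s ≤ ρ·SAR_eff·L_h²/(2k)` and
`R_T ≤ 1 + excess/ΔT_s`.  This is the same closed form the PDE solver is
tested against, so the bound and the solver cross-validate each other.
With the resin properties, SAR_eff = 0.8 W/kg and the representative
half-thickness range 2.5–3 mm, the excess is 0.0115–0.0166 K
(R_T ≤ 1.12–1.17) at a 0.1 K surface rise.  Note the arithmetic at
L = 2.5 mm gives 0.0115 K, not the lower figure sometimes quoted
alongside the 3 mm value; both ends are evaluated when a range is given.

## Synthetic thermography

The generator emulates the measurement structure, not camera physics:

- first-order lumped truth curve `ΔT = (P/hA)(1 − e^{−hA·t/mc})`;
- Gaussian camera noise, SD 0.05 K (the stated sensitivity; a
  heavy-tailed Student-t alternative is selectable);
- readout quantization to 0.1 K (the display resolution), applied after
  noise, half-away-from-zero with a 1e-9 relative nudge so decimal
  half-steps round up under binary floats; raw channels are stored too
  so tests can isolate quantization;
- ambient drift as a Gaussian random walk (default step SD 0.02 K per
  10-min step, consistent with a ±1 K ambient over an hour), shared
  within a trial between the exposed sample and a non-exposed reference
  channel — an idealization of co-located samples;
- baseline subtraction of the quantized t=0 reading, so every trial
  starts at exactly zero;
- 10 trials at 10-minute sampling over 60 minutes by default; identical
  seeds give bit-identical sets.

Presets: `implant-0.75A` is calibrated to the published implant behavior
(initial rate 4.44e-3 K/s, plateau 0.45 K; mass 0.05 kg and c = 500
J/(kg·K) are representative — only `P/mc` and `P/hA` are observable).
Against the published means the calibrated curve deviates at most
0.079 K (at the 10-min point, where the published mean undershoots its
own plateau) — within the display resolution but not within half of it.
`nonimplant-0.75A` uses the resin figures (5.55e-4 K/s, 0.05 K plateau);
`implant-0.1A` scales the absorbed power by the current ratio squared
((0.1/0.75)² ≈ 0.018, i.e. sub-resolution heating); `control` has no
excitation.

**Environmental correction** subtracts the reference channel pointwise.
It removes the shared drift exactly in the absence of quantization, but
doubles the camera-noise variance; it therefore reduces the variance of
trial means only when drift variance exceeds the per-channel
noise-plus-quantization variance (crossover near a 0.07 K drift step at
the default camera).  The variance-reduction property is tested in the
drift-dominated regime; below the crossover the correction still removes
systematic drift bias at the price of noise.

**Recovery ground truth.**  Because the measurement grid (10-min
sampling, 0–20 min window) samples the plateau as well as the rise, the
window-OLS slope of even a noiseless curve differs from `P/mc`.  The
recovery tests therefore score the estimator chain against the
*slope-referenced truth*: the same estimator applied to the noiseless
truth curve.  This isolates what the chain can control — noise, drift,
quantization, correction, aggregation — and the recovered median is
unbiased to ~1e-6 W/kg over 200 seeds, converging to exact recovery as
noise and quantization go to zero.  What passing these tests does *not*
show: anything about emissivity errors, pixel averaging, non-shared
drift, or the adequacy of the 20-min window for estimating `P/m` of a
fast-saturating body.

## Validation metrics

Simulated curves are linearly resampled at the measurement times and
scored with RMSE, MAE, maximum absolute error and Pearson r (constant
series raise rather than return 0).  The baseline point (exactly zero on
both sides by construction) is included by default and can be excluded;
metrics are displayed at two decimals with full precision in JSON.
Published metric values are carried in `reference.REPORTED_VALIDATION`
for context only — the underlying simulated series was never published,
so they are not test oracles.

## Problem sizes and numerical defaults

Default simulations are deliberately small: 1-D thermal meshes of 41–200
nodes, field lattices of order 10³ nodes, 200-seed recovery ensembles,
4e5-segment field oracles — each chosen as the coarsest size at which
the property being demonstrated is converged (second-order schemes
throughout; refinement tests in the suite document the margins).
Tolerances: field oracle agreement 1e-6 relative on-axis; loop closed
form 1e-4 at width/radius 1e-4; energy balance 1e-3 relative per step;
steady closed forms 5e-3.

## Known limitations

- No off-axis induced-E reconstruction, hence no true dielectrophoretic
  force map; `∇|B|²` is a stated surrogate.
- No 3-D anatomical geometry; the PDE solver is 1-D slab/cylinder.
- No magnetic materials (μr = 1 everywhere) and no temperature-dependent
  properties.
- The eddy model assumes a uniform axial field over the implant and
  full flux penetration; it degrades (flagged) beyond the skin-depth
  limit.
- The synthetic camera has no optics: no emissivity physics, no spatial
  averaging, no reflections.
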