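# Methods

This note documents the model, the numerical choices, the synthetic
boundary conditions, and the limits of what the test suite demonstrates.

## Wall model and tube law

The wall is a single-layer, incompressible, fibre-reinforced
hyperelastic cylinder. Three configurations matter conceptually —
stress-free (radially cut open ring), load-free (closed, residually
stressed) and loaded — but the kinematics map the stress-free state
directly onto the loaded one: with opening angle ω (closure factor
k = 2π/(2π−ω)) and net axial stretch λ_z, the loaded radius of the
material circle at stress-free radius R is
r² = (R²−R_i²)/(kλ_z) + r_i², so the entire wall state is a function of
the loaded inner radius alone. The intermediate load-free geometry is
never needed computationally and is not represented. Likewise only the
product λ_z = λ_z,res·λ_z,ext enters the equations, so the residual and
external axial stretches are not stored separately.

The strain energy is the exponential fibre-reinforced form with an
isotropic neo-Hookean ground matrix (parameters k₀, k₁, k₂, dispersion
weight α, fibre angles ±φ). Collagen fibres cannot support compression:
whenever I₄ⁱ < 1 the (I₄ⁱ−1) contribution of that family is zeroed in
the energy *and* in its derivatives, while the isotropic (1−α)(I₁−3)²
term inside the same exponential is retained. Energy derivatives are
analytic (chain rule through I₁ and I₄); tests verify them against
central finite differences everywhere, including one-sided checks across
the I₄ = 1 switch. Exponent arguments above 500 raise a diagnostic
error — such states are far outside any physiological regime and would
overflow double precision.

Radial equilibrium integrated through the thickness gives the
transmural pressure as a 1D integral over the stress-free radial
coordinate (the tube law) and the reduced axial force as a second
integral. Both use composite Simpson quadrature on 21 uniform radial
nodes by default (user-configurable); tests assert <0.1% agreement with
201 nodes over the 10–200 mmHg working range, and agreement of the
stress-free-coordinate and loaded-coordinate forms of the equilibrium
integral on 100 random admissible states. Note that outside the working
range the exponential law becomes astronomically steep (pressures grow
by tens of orders of magnitude within a factor 2 of area), so quadrature
statements are made — and meaningful — only at physiological loads.

Through-thickness Cauchy stresses integrate the radial-equilibrium ODE
cumulatively (trapezoid on the same node set) from σ_rr(r_i) = −P_in;
the hoop and axial components follow from the constitutive differences
and the Lagrange multiplier is recovered algebraically. The outer
boundary closes at −P_ext to quadrature accuracy, and a thin-walled
stiff-cylinder limit reproduces the Laplace law within 5%.

Units are CGS internally (cm, g, s, dyn/cm²; 1 mmHg = 1333.22 dyn/cm²,
1 kPa = 10⁴ dyn/cm²). Files and tables use kPa, degrees and mmHg;
conversion happens only at I/O.

## Reference parameters

Two published CCA parameter sets are built in: the biaxial
extension–inflation fit (H = 0.117 cm, R_i = 0.431 cm, ω = 80.9°,
k₀ = 26.6 kPa, k₁ = 20.9 kPa, k₂ = 56.5, α = 0.97, φ = ±24.9°,
the package default) and an inflation-test fit (isotropic, α = 0,
φ = ±90°). Blood: ρ = 1.06 g/cm³, μ = 0.04 poise. Stress-free length
L = 9 cm; the fluid mesh spans the loaded length l = λ_z·L by default
(12.6 cm at λ_z = 1.4, 14 uniform elements), with a config switch to
mesh the stress-free length instead. External pressure defaults to zero.

Three "virtual arteries" VA1–VA3 scale R_i and ω to 80%, 90% and 110%
of the reference (VA1: R_i = 0.3448 cm, ω = 64.72°; VA2: 0.3879 cm,
72.81°; VA3: 0.4741 cm, 88.99°) with all other parameters unchanged.

## Flow solver

The conservation equations are integrated element-wise with the
trapezoidal rule in space and a second-order backward difference in
time; convection and Poiseuille friction are explicit at the previous
level, as is the compliance (central finite difference with
ε = 10⁻⁸ cm²), so each step is one linear solve in the 2N nodal
unknowns. The inlet prescribes flow; the Windkessel capacitor ODE is
discretized with the same backward-difference weights and eliminated
into the outlet row (tests confirm the composite update is genuinely
second order: halving dt cuts the outlet error ~4× against a tight ODE
solve). After each step, nodal areas are recovered from the tube law by
the compliance-preconditioned secant iteration to 10⁻⁶ cm² (cap 100
iterations, warning at 50); a bisection oracle confirms the recovered
areas.

Startup: pressure uniform at 80 mmHg, zero flow, areas from the secant
inversion, capacitor at P_init − R₁Q_in(0); the first step after any
time-step change uses backward Euler. The time step is dt = CFL·l_e/c_max
with CFL = 2.5, held fixed within a cardiac cycle, recomputed between
cycles from the previous cycle's maximum intrinsic wave speed, and
rounded so an integer number of steps tiles the period (this makes
cycle-to-cycle comparisons exact). The first cycle's realized CFL can
overshoot (the initial wave-speed estimate predates the systolic
maximum); from the second cycle it stays within [2, 3]. Ten cycles are
simulated; the max-norm pressure difference between the last two cycles
is reported as the periodicity residual (≈4×10⁻⁵ mmHg for the reference
run) and decreases monotonically once the step size has settled.

Problem sizes: a 10-cycle reference run is ~670 steps/cycle and takes a
few seconds; the refinement check doubles the element count and halves
the CFL and requires PWV stability within 2%.

## Boundary conditions (synthetic)

The packaged defaults do not reproduce any measured waveform. The
inflow is parametric: a raised-cosine systolic pulse on a diastolic
baseline, period 1.1 s, mean 6.5 ml/s, peak 21 ml/s, systolic fraction
0.3 — typical resting CCA values. The Windkessel coefficients
(R₁ = 2.5×10³, C = 4.6×10⁻⁵, R₂ = 1.72×10⁴ CGS, P_out = 0) were
calibrated once so that the reference wall operates at the published
resting carotid point (diastole ≈79 mmHg, systole ≈130 mmHg; R₁ near
the characteristic impedance to limit outlet reflection) and are frozen
thereafter — they are not re-tuned per scenario, and the increased-flow
state (inflow ×1.30) deliberately reuses them. What the synthetic
waveform does not emulate: the dicrotic notch, beat-to-beat
variability, and measured spectral content; consequences for transit
timing are bounded by the ±10% agreement demonstrated on the published
PWV values.

## Indices

Cycle extrema use parabolic sub-sample refinement (the solver grid at
CFL 2.5 is ~1.6 ms). Distensibility and Bramwell–Hill PWV follow their
definitions exactly; tests recompute every published axial-stretch row
to 0.5%.

Foot-to-foot PWV is measured between inlet and outlet over the full
fluid length. Two foot definitions are provided: the refined cycle
minimum, and the intersecting tangent (crossing of the horizontal
through the minimum with the tangent at the steepest upstroke). The
**tangent is the pipeline default**. This was a deliberate, evidence-led
choice: with the minimum foot, the simulated transit speed essentially
equals the intrinsic diastolic wave speed for every geometry, which
reproduces the reference vessel (8.7 vs 8.57 m/s published) but not the
published virtual-artery values (8.2 vs 6.09 m/s for VA1) — and the
published VA1 linear-law row itself implies an intrinsic diastolic
speed of 8.5 m/s against a printed transit of 6.12 m/s, so the printed
transit cannot be the minimum-foot speed. The tangent foot, which is
sensitive to the reflection-induced reshaping of the upstroke along the
vessel, lands all published transit speeds within 10% (reference 8.85
vs 8.57; VA1 6.67 vs 6.09; VA2 7.73 vs 7.33; VA3 9.98 vs 9.92) and
preserves the monotone decrease of PWV with axial stretch. One known
residual: the *signs* of the small PWV differences between the linear
surrogates and the hyperelastic model are not reproduced under the
tangent foot (magnitudes stay within the published 11% envelope, and
the pressure/area error sign pattern — β_d overestimating systolic
area, underestimating systolic pressure — is reproduced); under the
minimum foot the β_d sign matches instead but the VA transit levels do
not. No single foot definition recovers both, so the choice favours the
absolute transit speeds and is exposed as a config option
(`run.foot_method`).

## Linear-law calibration

β_d = 2√A_d/C_A(A_d); β_a = 2√A_d/C_Aa with C_Aa the uniform-in-A
trapezoidal mean of C_A over [A_d, A_s] on 101 points. Both laws are
anchored at the hyperelastic diastolic point (A_ref, P_ref) =
(A_d, P̄(A_d)) so they agree with the source at diastole exactly; since
the carotid stiffens with area, C_Aa < C_Ad and hence β_a > β_d. Both
calibrations are computed from the normal-flow hyperelastic run and are
not recomputed for increased flow.

## Sensitivity analysis

Sobol indices of PWV with respect to (H, R_i, ω, k₀, k₁, k₂, α, φ), λ_z
fixed at 1.4. Bounds: ±5% of the reference values, α ∈ [0.95, 1.00];
the φ bound applies to the magnitude and the families stay symmetric.
Sampling draws one scrambled Sobol' stream of dimension 2×8 and splits
it into the A and B blocks; estimators are pick-freeze with Jansen
forms by default (the covariance forms are available), at cost
n(k+2) model evaluations; failed evaluations are discarded pairwise
(abort above 1% failures). The machinery is validated against analytic
additive models, the Ishigami function's closed-form indices, and a
brute-force double-loop conditional-variance oracle.

Two PWV models exist. The `static` model (intrinsic wave speed at the
diastolic working point) is fast but **does not reproduce the transit
ranking** — it makes wall thickness as influential as the inner radius,
because at fixed pressure a thicker wall directly stiffens the local
law. The `simulation` model (full transient run + tangent-foot transit)
is the meaningful one: the measured transit is dominated by geometry
through the operating area and outlet reflection, and yields the
published ordering — inner radius first by both first-order and total
indices, opening angle second — stably even at small sample sizes
(verified across scramble seeds at n = 8 with 4 cycles, 10 elements,
11 quadrature nodes; a full-fidelity study is a CLI call away but costs
n(k+2) transient runs). The published *fine* ordering among the
near-zero-effect parameters (which places thickness strictly last in
total variance) is not reproduced by the smooth model at any sample
size: thickness's variance contribution, while small, genuinely exceeds
the stiffness constants' here. The corresponding published total-index
values co-exist with first-order indices below 10⁻⁴, a signature of
evaluation noise dominating that part of the published table; the
package does not emulate that noise, and the strict thickness-last
check in the acceptance tests is expected to fail — it is retained,
unweakened, as an honest record of the discrepancy.

## What the tests do and do not show

All expensive checks run at reduced, stated problem sizes (10-cycle
runs, n = 8 sensitivity, single-artery error tables); agreement with
the published values is demonstrated at 10% for transit speeds, 0.5%
for the index arithmetic, and sign/envelope level for the surrogate
error tables. Passing tests show the implementation is internally
consistent (conservation, coordinate invariance, closed-form limits,
independent oracles) and consistent with the published study at those
tolerances under *synthetic* boundary conditions; they do not validate
the model against in-vivo measurements, multi-vessel networks,
viscoelastic or actively contracting walls, which are out of scope.
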