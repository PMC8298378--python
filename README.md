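# elastotube

One-dimensional pulse-wave haemodynamics of the human common carotid
artery (CCA) closed by a three-dimensionally derived, fibre-reinforced
hyperelastic wall model — with residual stress, axial pre-stretch,
linear tube-law surrogates, clinical stiffness indices and global
sensitivity analysis.

It is written for cardiovascular-biomechanics researchers who want a 1D
blood-flow solver whose pressure–area closure comes from an actual
constitutive description of the vessel wall rather than an empirical
tube law, and who want to quantify how the wall's structural parameters
shape measurable haemodynamics such as the local pulse wave velocity
(PWV).

## The model

**Wall.** The vessel wall is an incompressible thick-walled cylinder
reinforced by two helical collagen-fibre families at ±φ from the
circumferential direction. Circumferential residual stress is encoded by
the opening angle ω of the radially cut ring (closure factor
k = 2π/(2π−ω)) and the vessel carries a net axial stretch λ_z. The
strain energy is of Holzapfel–Ogden type,

    Ψ = k₀(I₁−3) + k₁/(2k₂) Σᵢ { exp[k₂((1−α)(I₁−3)² + α⟨I₄ⁱ−1⟩²)] − 1 },

where I₁ = λ_r²+λ_θ²+λ_z², I₄ⁱ = λ_θ²cos²φⁱ + λ_z²sin²φⁱ, and fibres
carry load only in tension (the ⟨I₄−1⟩ term is dropped when I₄ < 1).
Integrating radial equilibrium through the thickness yields the
**hyperelastic tube law** — transmural pressure as an algebraic function
of lumen area,

    P − P_ext = ∫ (λ_θ ∂Ψ/∂λ_θ − λ_r ∂Ψ/∂λ_r) / (λ_θ λ_z r) dR,

plus the reduced axial force F_z and the full through-thickness Cauchy
stress field.

**Flow.** Cross-sectionally averaged mass and momentum conservation
(Poiseuille friction) for pressure P and flow Q on a single segment,

    C_A ∂P/∂t + ∂Q/∂z = 0,
    (ρ/A) ∂Q/∂t + ∂P/∂z = −(ρ/A) ∂(Q²/A)/∂z − 8πμQ/A²,

closed by any tube law through the compliance C_A = ∂A/∂P, integrated
with an implicit sub-domain collocation scheme (trapezoidal in space,
BDF2 in time, secant area recovery, adaptive time step at CFL ≈ 2.5).
A prescribed periodic inflow drives the inlet; a three-element
(R₁, C, R₂) Windkessel closes the outlet.

**Indices and sensitivity.** Systolic/diastolic extraction,
distensibility D = (ΔA/A_d)/ΔP, Bramwell–Hill PWV = 1/√(ρD),
foot-to-foot transit PWV, calibration of the classical linear law
P = P_ref + β(√A − √A_ref) against the hyperelastic model (β_d from
diastolic compliance, β_a from range-averaged compliance), and
variance-based Sobol sensitivity of PWV to the eight wall parameters
(pick-freeze estimators on scrambled Sobol' sequences).

## Worked example

The reference wall (healthy human CCA biaxial fit: H = 0.117 cm,
R_i = 0.431 cm, ω = 80.9°, k₀ = 26.6 kPa, k₁ = 20.9 kPa, k₂ = 56.5,
α = 0.97, φ = ±24.9°) at the in-vivo stretch λ_z = 1.4:

```python
from elastotube import WallParameters, transmural_pressure
from elastotube.bench import simulate_wall
from elastotube.units import MMHG

wall = WallParameters.sommer_cca()            # lambda_z = 1.4
print(transmural_pressure(0.3303, wall) / MMHG)
# 79.02  -> the diastolic pressure (mmHg) at the diastolic lumen area

summary, state = simulate_wall(wall)          # 10-cycle transient run
print(summary.P_d, summary.P_s)               # 78.45 128.47  (mmHg)
print(summary.A_d, summary.dA)                # 0.3300 0.0173 (cm^2)
print(summary.PWV_foot, summary.PWV_BH)       # 8.85 10.97    (m/s)
```

The transient run uses the packaged boundary conditions (a synthetic
resting inflow, mean 6.5 ml/s at 1.1 s period, and Windkessel
coefficients calibrated to the resting carotid operating point): the
vessel settles at 78/128 mmHg, distends by 0.0173 cm² per beat, and
transmits the pressure foot at 8.9 m/s — slower than the Bramwell–Hill
estimate of 11.0 m/s, as expected, since the foot travels at the
diastolic (softest) wave speed.

Identifying the in-vivo axial stretch from the bench:

```sh
$ elastotube invivo-stretch
lambda_z=1.200: force spread 4.579e+04 dyn
lambda_z=1.300: force spread 2.548e+04 dyn
lambda_z=1.400: force spread 856.4 dyn
lambda_z=1.500: force spread 3.353e+04 dyn
in-vivo stretch: 1.4
```

At λ_z = 1.4 the axial force is essentially independent of luminal
pressure (spread 856 dyn against tens of thousands elsewhere) — the
hallmark of the physiological axial stretch.

Other CLI entry points: `elastotube simulate`, `biaxial`, `scenario
--va {1,2,3} [--increased-flow]`, `sobol`, `synth-inflow` (see
`elastotube --help`; configuration via a YAML file layered over the
packaged reference, `src/elastotube/data/reference_cca.yaml`).

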