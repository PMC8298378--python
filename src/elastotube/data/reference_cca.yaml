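# Reference common-carotid configuration.
#
# Wall: healthy human CCA, extension-inflation biaxial fit; angles in
# degrees, stiffnesses in kPa, lengths in cm. Boundary conditions are
# SYNTHETIC: a parametric resting inflow plus three-element Windkessel
# coefficients (CGS) calibrated once so this wall operates at resting
# carotid pressures (~79/130 mmHg).
wall:
  H: 0.117          # stress-free thickness, cm
  R_i: 0.431        # stress-free inner radius, cm
  L: 9.0            # stress-free length, cm
  omega_deg: 80.9   # opening angle, degrees
  lambda_z: 1.4     # net axial stretch (in-vivo)
  k0_kpa: 26.6      # isotropic stiffness, kPa
  k1_kpa: 20.9      # fibre stiffness, kPa
  k2: 56.5          # fibre exponent
  alpha: 0.97       # dispersion weight
  phi_deg: 24.9     # fibre angle magnitude (families at +/-phi), degrees

fluid:
  rho: 1.06         # g/cm^3
  mu: 0.04          # poise

mesh:
  n_elements: 14
  use_stress_free_length: false   # true: mesh spans L instead of lambda_z*L

bcs:
  inflow:           # synthetic parametric resting-CCA waveform
    mean_q: 6.5     # cm^3/s
    peak_q: 21.0    # cm^3/s
    period: 1.1     # s
    systolic_fraction: 0.3
  windkessel:       # CGS; synthetic, calibrated to the resting operating point
    R1: 2.5e3       # dyn s / cm^5
    C: 4.6e-5       # cm^5 / dyn
    R2: 1.72e4      # dyn s / cm^5
    P_out: 0.0      # dyn / cm^2

run:
  n_cycles: 10
  cfl: 2.5
  quad_n: 21        # radial Simpson nodes for the wall integrals
  p_init_mmhg: 80.0
  foot_method: tangent   # or: minimum

sensitivity:
  rel_box: 0.05
  alpha_range: [0.95, 1.00]
  n_samples: 1024
  estimator: jansen
  model: static     # or: simulation
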