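"""Fibre-reinforced hyperelastic artery wall and the tube law it induces.

The vessel wall is a thick-walled, incompressible, hyperelastic cylinder
reinforced by ``n_f`` helical collagen-fibre families, with circumferential
residual stress represented through the opening angle of the radially cut
ring and an imposed net axial stretch. The kinematics map a stress-free
configuration (inner radius R_i, thickness H, opening angle omega) onto the
loaded configuration parameterized solely by the loaded inner radius r_i,
so the whole wall state — principal stretches, strain invariants, Cauchy
stresses — is an algebraic function of lumen area.

Strain energy (Holzapfel–Ogden type, per unit reference volume):

    Psi = k0*(I1 - 3)
        + k1/(2*k2) * sum_i { exp[k2*((1-alpha)*(I1-3)^2
                                      + alpha*<I4^i - 1>^2)] - 1 }

where I1 is the first invariant of C = F^T F, I4^i the squared stretch
along fibre family i, and <.> denotes the tension-only switch: fibres
cannot sustain compression, so the (I4^i - 1) contribution is dropped
(in the energy and its derivatives) whenever I4^i < 1. The isotropic
(1-alpha)*(I1-3)^2 term inside the same exponential is always retained.

Radial equilibrium integrated through the thickness gives the transmural
pressure as a one-dimensional integral over the stress-free radial
coordinate — the hyperelastic tube law — and the axial force as a second
such integral. Both are evaluated with composite Simpson quadrature.

All quantities are CGS; see :mod:`elastotube.units`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.integrate import cumulative_trapezoid, simpson

from .tube_laws import TubeLaw
from .units import KPA

__all__ = [
    "WallParameters",
    "FluidProperties",
    "StretchState",
    "StressProfile",
    "deformed_radius",
    "principal_stretches",
    "strain_invariants",
    "sef_and_derivatives",
    "transmural_pressure",
    "transmural_pressure_loaded_coords",
    "axial_force",
    "stress_profile",
    "compliance_fd",
    "wave_speed",
    "HyperelasticTubeLaw",
]

# largest admissible exponent argument inside the fibre exponential;
# beyond this the state is far outside any physiological regime and the
# energy would overflow double precision
_EXP_CAP = 500.0


@dataclass(frozen=True)
class WallParameters:
    """Structural parameters of one virtual artery (stress-free geometry
    plus constitutive constants). Angles are radians internally; stiffnesses
    are dyn/cm^2.

    ``lambda_z`` is the net axial stretch, the product of the residual and
    externally imposed axial stretches; only the product enters the
    kinematics, so the pair is not stored separately.
    """

    H: float  # stress-free wall thickness, cm
    R_i: float  # stress-free inner radius, cm
    omega: float  # opening angle, rad
    lambda_z: float  # net axial stretch
    k0: float  # isotropic stiffness, dyn/cm^2
    k1: float  # fibre stiffness, dyn/cm^2
    k2: float  # fibre exponent
    alpha: float  # dispersion weight in [0, 1]
    phi: tuple = (0.0,)  # fibre-family angles from circumferential, rad
    L: float = 9.0  # stress-free length, cm

    def __post_init__(self):
        if self.H <= 0 or self.R_i <= 0 or self.L <= 0:
            raise ValueError("H, R_i and L must be positive")
        if not 0.0 <= self.omega < 2 * math.pi:
            raise ValueError("opening angle must lie in [0, 2*pi)")
        if self.lambda_z <= 0:
            raise ValueError("lambda_z must be positive")
        if self.k0 < 0 or self.k1 < 0:
            raise ValueError("k0 and k1 must be non-negative")
        if self.k2 <= 0:
            raise ValueError("k2 must be positive")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        object.__setattr__(self, "phi", tuple(float(p) for p in self.phi))

    @property
    def n_f(self) -> int:
        """Number of fibre families."""
        return len(self.phi)

    @property
    def k(self) -> float:
        """Opening-angle closure factor k = 2*pi/(2*pi - omega) >= 1."""
        return 2 * math.pi / (2 * math.pi - self.omega)

    @property
    def loaded_length(self) -> float:
        """Axial length under load, l = lambda_z * L (cm)."""
        return self.lambda_z * self.L

    def replace(self, **kw) -> "WallParameters":
        return replace(self, **kw)

    @classmethod
    def from_io_units(
        cls,
        H: float,
        R_i: float,
        omega_deg: float,
        k0_kpa: float,
        k1_kpa: float,
        k2: float,
        alpha: float,
        phi_deg: Sequence[float] | float,
        lambda_z: float = 1.4,
        L: float = 9.0,
    ) -> "WallParameters":
        """Build from file/table units (degrees, kPa).

        A scalar ``phi_deg`` is expanded to the symmetric pair ±phi.
        """
        if np.isscalar(phi_deg):
            phi_deg = (float(phi_deg), -float(phi_deg))
        return cls(
            H=H,
            R_i=R_i,
            omega=math.radians(omega_deg),
            lambda_z=lambda_z,
            k0=k0_kpa * KPA,
            k1=k1_kpa * KPA,
            k2=k2,
            alpha=alpha,
            phi=tuple(math.radians(p) for p in phi_deg),
            L=L,
        )

    @classmethod
    def sommer_cca(cls, lambda_z: float = 1.4, L: float = 9.0) -> "WallParameters":
        """Healthy human common carotid, extension-inflation biaxial fit."""
        return cls.from_io_units(
            H=0.117, R_i=0.431, omega_deg=80.9, k0_kpa=26.6, k1_kpa=20.9,
            k2=56.5, alpha=0.97, phi_deg=24.9, lambda_z=lambda_z, L=L,
        )

    @classmethod
    def delfino_cca(cls, lambda_z: float = 1.4, L: float = 9.0) -> "WallParameters":
        """Human common carotid, inflation-test fit (isotropic: alpha = 0)."""
        return cls.from_io_units(
            H=0.09, R_i=0.446, omega_deg=100.0, k0_kpa=15.91, k1_kpa=58.3,
            k2=9.8, alpha=0.0, phi_deg=90.0, lambda_z=lambda_z, L=L,
        )


@dataclass(frozen=True)
class FluidProperties:
    """Blood density (g/cm^3) and dynamic viscosity (poise)."""

    rho: float = 1.06
    mu: float = 0.04

    def __post_init__(self):
        if self.rho <= 0 or self.mu <= 0:
            raise ValueError("rho and mu must be positive")


@dataclass(frozen=True)
class StretchState:
    """Principal stretches and strain invariants at one or more radial
    stations. ``I4`` has the fibre-family axis first: shape (n_f, ...)."""

    lambda_r: np.ndarray
    lambda_theta: np.ndarray
    lambda_z: np.ndarray
    I1: np.ndarray
    I4: np.ndarray


@dataclass(frozen=True)
class StressProfile:
    """Through-thickness Cauchy stress field of a loaded wall."""

    R_nodes: np.ndarray  # stress-free radial stations, cm
    r_nodes: np.ndarray  # loaded radii, cm
    sigma_rr: np.ndarray  # dyn/cm^2
    sigma_theta: np.ndarray
    sigma_zz: np.ndarray
    p: np.ndarray  # Lagrange-multiplier pressure


def deformed_radius(R, r_i, wall: WallParameters):
    """Loaded radius r of the material circle at stress-free radius R.

    Incompressibility of the closed, axially stretched tube gives
    r^2 = (R^2 - R_i^2)/(k*lambda_z) + r_i^2, which preserves the wall
    volume pi*(r^2 - r_i^2)*k*lambda_z = pi*(R^2 - R_i^2) exactly.
    """
    R = np.asarray(R, dtype=float)
    rad = (R**2 - wall.R_i**2) / (wall.k * wall.lambda_z) + np.square(r_i)
    if np.any(rad <= 0):
        raise ValueError("invalid geometry: non-positive deformed radius")
    return np.sqrt(rad)


def principal_stretches(R, r_i, wall: WallParameters) -> StretchState:
    """Principal stretches and invariants at stress-free radius R.

    lambda_r = R/(r*k*lambda_z), lambda_theta = k*r/R, lambda_z fixed;
    the product is one by construction (incompressibility).
    """
    R = np.asarray(R, dtype=float)
    r = deformed_radius(R, r_i, wall)
    k, lz = wall.k, wall.lambda_z
    lam_r = R / (r * k * lz)
    lam_t = k * r / R
    lam_z = np.broadcast_to(np.asarray(lz, dtype=float), lam_r.shape)
    I1 = lam_r**2 + lam_t**2 + lz**2
    phi = np.asarray(wall.phi, dtype=float)
    cos2 = np.cos(phi) ** 2
    sin2 = np.sin(phi) ** 2
    # family axis first
    I4 = (
        lam_t[np.newaxis, ...] ** 2 * cos2.reshape((-1,) + (1,) * lam_t.ndim)
        + lz**2 * sin2.reshape((-1,) + (1,) * lam_t.ndim)
    )
    return StretchState(lambda_r=lam_r, lambda_theta=lam_t, lambda_z=lam_z,
                        I1=I1, I4=I4)


def strain_invariants(state: StretchState, wall: WallParameters):
    """(I1, I4 per family) of a stretch state."""
    return state.I1, state.I4


def sef_and_derivatives(state: StretchState, wall: WallParameters):
    """Strain energy Psi and its partial derivatives w.r.t. the three
    principal stretches, with the tension-only fibre switch applied.

    Returns ``(Psi, dPsi_dlr, dPsi_dlt, dPsi_dlz)``, each shaped like the
    input stretches. Derivatives are analytic (chain rule through I1 and
    I4); the fibre term of any family with I4 < 1 contributes nothing to
    either the energy or the derivatives.
    """
    lr, lt, lz = state.lambda_r, state.lambda_theta, state.lambda_z
    I1, I4 = state.I1, state.I4
    k0, k1, k2, alpha = wall.k0, wall.k1, wall.k2, wall.alpha

    psi = k0 * (I1 - 3.0)
    d_lr = 2.0 * k0 * lr
    d_lt = 2.0 * k0 * lt
    d_lz = 2.0 * k0 * lz

    phi = np.asarray(wall.phi, dtype=float)
    for i in range(wall.n_f):
        e4 = np.where(I4[i] > 1.0, I4[i] - 1.0, 0.0)  # tension-only
        E = (1.0 - alpha) * (I1 - 3.0) ** 2 + alpha * e4**2
        arg = k2 * E
        if np.any(arg > _EXP_CAP):
            raise OverflowError(
                "fibre exponential overflow: k2*E = "
                f"{float(np.max(arg)):.3g} exceeds {_EXP_CAP:g}; "
                "stretch state far outside the admissible range"
            )
        ex = np.exp(arg)
        psi = psi + (k1 / (2.0 * k2)) * (ex - 1.0)
        # dE/dlambda_j = 2(1-alpha)(I1-3) dI1/dlambda_j + 2 alpha <I4-1> dI4/dlambda_j
        common = 2.0 * (1.0 - alpha) * (I1 - 3.0)
        cos2, sin2 = math.cos(phi[i]) ** 2, math.sin(phi[i]) ** 2
        d_lr = d_lr + (k1 / 2.0) * ex * (common * 2.0 * lr)
        d_lt = d_lt + (k1 / 2.0) * ex * (
            common * 2.0 * lt + 2.0 * alpha * e4 * 2.0 * lt * cos2
        )
        d_lz = d_lz + (k1 / 2.0) * ex * (
            common * 2.0 * lz + 2.0 * alpha * e4 * 2.0 * lz * sin2
        )
    return psi, d_lr, d_lt, d_lz


def _radial_nodes(wall: WallParameters, quad_n: int) -> np.ndarray:
    if quad_n < 3 or quad_n % 2 == 0:
        raise ValueError("quad_n must be odd and >= 3 (composite Simpson)")
    return np.linspace(wall.R_i, wall.R_i + wall.H, quad_n)


def transmural_pressure(A, wall: WallParameters, quad_n: int = 21):
    """Hyperelastic tube law: transmural pressure P - P_ext (dyn/cm^2) at
    lumen area A (cm^2).

    Radial equilibrium integrated through the thickness, with the
    integration variable changed to the stress-free radius:

        P - P_ext = int_{R_i}^{R_i+H}
            (lt*dPsi/dlt - lr*dPsi/dlr) / (lt*lz*r) dR

    evaluated by composite Simpson on ``quad_n`` uniform nodes. Vectorized
    over ``A``.
    """
    shape = np.shape(A)
    A_arr = np.atleast_1d(np.asarray(A, dtype=float)).ravel()
    if np.any(A_arr <= 0):
        raise ValueError("lumen area must be positive")
    r_i = np.sqrt(A_arr / np.pi)  # (m,)
    R = _radial_nodes(wall, quad_n)  # (q,)
    state = principal_stretches(R[np.newaxis, :], r_i[:, np.newaxis], wall)
    _, d_lr, d_lt, d_lz = sef_and_derivatives(state, wall)
    r = deformed_radius(R[np.newaxis, :], r_i[:, np.newaxis], wall)
    integrand = (state.lambda_theta * d_lt - state.lambda_r * d_lr) / (
        state.lambda_theta * wall.lambda_z * r
    )
    out = simpson(integrand, x=R, axis=-1)
    return out.reshape(shape) if shape else float(out[0])


def transmural_pressure_loaded_coords(A, wall: WallParameters, quad_n: int = 21):
    """Same equilibrium integral evaluated in loaded coordinates r on
    [r_i, r_i + h]: int (lt*dPsi/dlt - lr*dPsi/dlr)/r dr.

    Serves as the change-of-variables cross-check of
    :func:`transmural_pressure`; both must agree to quadrature tolerance.
    """
    A_arr = np.atleast_1d(np.asarray(A, dtype=float))
    if np.any(A_arr <= 0):
        raise ValueError("lumen area must be positive")
    r_i = np.sqrt(A_arr / np.pi)
    r_o = deformed_radius(wall.R_i + wall.H, r_i, wall)
    out = np.empty_like(A_arr)
    for j, (ri, ro) in enumerate(zip(r_i, np.atleast_1d(r_o))):
        r = np.linspace(ri, ro, quad_n)
        # invert the incompressible mapping for the material coordinate
        R = np.sqrt((r**2 - ri**2) * wall.k * wall.lambda_z + wall.R_i**2)
        state = principal_stretches(R, ri, wall)
        _, d_lr, d_lt, _ = sef_and_derivatives(state, wall)
        integrand = (state.lambda_theta * d_lt - state.lambda_r * d_lr) / r
        out[j] = simpson(integrand, x=r)
    return out if np.ndim(A) else float(out[0])


def axial_force(r_i, wall: WallParameters, quad_n: int = 21):
    """Reduced axial force F_z (dyn) on the stretched, pressurized tube:

        F_z = pi * int_{R_i}^{R_i+H}
            (2*lz*dPsi/dlz - lt*dPsi/dlt - lr*dPsi/dlr) * r/(lt*lz) dR
    """
    r_i_arr = np.atleast_1d(np.asarray(r_i, dtype=float))
    if np.any(r_i_arr <= 0):
        raise ValueError("loaded inner radius must be positive")
    R = _radial_nodes(wall, quad_n)
    state = principal_stretches(R[np.newaxis, :], r_i_arr[:, np.newaxis], wall)
    _, d_lr, d_lt, d_lz = sef_and_derivatives(state, wall)
    r = deformed_radius(R[np.newaxis, :], r_i_arr[:, np.newaxis], wall)
    integrand = (
        (2.0 * wall.lambda_z * d_lz - state.lambda_theta * d_lt
         - state.lambda_r * d_lr)
        * r
        / (state.lambda_theta * wall.lambda_z)
    )
    out = np.pi * simpson(integrand, x=R, axis=-1)
    return out if np.ndim(r_i) else float(out[0])


def stress_profile(
    r_i: float,
    wall: WallParameters,
    P_in: float,
    P_ext: float = 0.0,
    quad_n: int = 21,
) -> StressProfile:
    """Through-thickness Cauchy stresses of the loaded wall.

    sigma_rr is obtained by integrating the radial equilibrium
    d(sigma_rr) = (sigma_theta - sigma_rr)/r dr from the lumen with
    sigma_rr(r_i) = -P_in; the hoop and axial components follow from the
    constitutive differences, and the Lagrange multiplier p is recovered
    from sigma_rr = lambda_r dPsi/dlambda_r - p.
    """
    R = _radial_nodes(wall, quad_n)
    state = principal_stretches(R, float(r_i), wall)
    _, d_lr, d_lt, d_lz = sef_and_derivatives(state, wall)
    r = deformed_radius(R, float(r_i), wall)
    diff_tr = state.lambda_theta * d_lt - state.lambda_r * d_lr
    diff_zr = state.lambda_z * d_lz - state.lambda_r * d_lr
    sigma_rr = -P_in + cumulative_trapezoid(diff_tr / r, r, initial=0.0)
    sigma_theta = sigma_rr + diff_tr
    sigma_zz = sigma_rr + diff_zr
    p = state.lambda_r * d_lr - sigma_rr
    return StressProfile(
        R_nodes=R, r_nodes=r, sigma_rr=sigma_rr,
        sigma_theta=sigma_theta, sigma_zz=sigma_zz, p=p,
    )


def compliance_fd(A, tube_law: TubeLaw, eps: float = 1e-8):
    """Central finite-difference compliance C_A = dA/dP of any tube law."""
    return tube_law.compliance(A, eps=eps)


def wave_speed(A, tube_law: TubeLaw, fluid: FluidProperties):
    """Intrinsic wave speed c = sqrt(A/(rho*C_A)) in cm/s."""
    return tube_law.wave_speed(A, fluid.rho)


class HyperelasticTubeLaw(TubeLaw):
    """Tube law induced by the fibre-reinforced wall model.

    Pressure comes from :func:`transmural_pressure`; compliance from the
    central finite difference of the TubeLaw base (the law is strongly
    nonlinear in A, so no useful closed form exists).
    """

    def __init__(self, wall: WallParameters, quad_n: int = 21,
                 p_ext: float = 0.0):
        self.wall = wall
        self.quad_n = quad_n
        self.p_ext = p_ext

    def pressure(self, A):
        return transmural_pressure(A, self.wall, self.quad_n)

    def area_from_pressure(
        self, P_transmural: float, bracket: tuple | None = None
    ) -> float:
        """Scalar inverse of the tube law by bracketed root finding.

        Used by the virtual-experiment bench; the flow solver uses the
        faster secant update instead.
        """
        from scipy.optimize import brentq

        A0 = np.pi * self.wall.R_i**2
        if bracket is None:
            # expand multiplicatively from the stress-free area; states
            # deep in compression overflow the fibre exponential, which
            # here means the target is below the attainable range
            def f(a):
                return transmural_pressure(a, self.wall, self.quad_n)

            lo = hi = A0
            try:
                f_lo = f_hi = f(A0)
            except OverflowError as exc:
                raise ValueError(
                    "reference area not evaluable for this wall"
                ) from exc
            while f_lo > P_transmural:
                new = 0.8 * lo
                try:
                    f_lo = f(new)
                except OverflowError as exc:
                    raise ValueError(
                        "pressure outside attainable range (wall in "
                        "compression)"
                    ) from exc
                lo = new
                if lo < 1e-3 * A0:
                    raise ValueError("pressure outside attainable range")
            while f_hi < P_transmural:
                hi *= 1.3
                f_hi = f(hi)
                if hi > 50 * A0:
                    raise ValueError("pressure outside attainable range")
        else:
            lo, hi = bracket
        return brentq(
            lambda a: transmural_pressure(a, self.wall, self.quad_n)
            - P_transmural,
            lo, hi, xtol=1e-12,
        )
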