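"""Tube laws: the algebraic closure relating lumen area to transmural pressure.

A tube law is any object mapping lumen area A (cm^2) to transmural pressure
P - P_ext (dyn/cm^2), together with its compliance C_A = dA/dP and the
intrinsic wave speed c = sqrt(A / (rho * C_A)). The 1D solver is agnostic to
which law closes the conservation equations.

Two families are provided:

* :class:`~elastotube.wall.HyperelasticTubeLaw` — derived from the 3D
  fibre-reinforced wall model (see :mod:`elastotube.wall`);
* :class:`LinearTubeLaw` — the classical law P = P_ref + beta*(sqrt(A) -
  sqrt(A_ref)), linear in the lumen radius, with two calibrations against a
  nonlinear source law: ``beta_d`` matches the source compliance at the
  diastolic area, ``beta_a`` matches the compliance averaged over the
  diastolic-systolic area range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class TubeLaw:
    """Contract shared by all tube laws.

    Subclasses implement :meth:`pressure`; generic finite-difference
    compliance and the wave-speed relation are inherited (and may be
    overridden by closed forms).
    """

    #: external pressure acting on the outer wall surface (dyn/cm^2)
    p_ext: float = 0.0

    def pressure(self, A):
        """Transmural pressure P - P_ext (dyn/cm^2) at lumen area A (cm^2)."""
        raise NotImplementedError

    def compliance(self, A, eps: float = 1e-8):
        """C_A = dA/dP by central finite difference with step ``eps`` (cm^2)."""
        scalar = np.ndim(A) == 0
        A = np.atleast_1d(np.asarray(A, dtype=float))
        if np.any(A - eps <= 0):
            raise ValueError("area too small for finite-difference compliance")
        P = np.asarray(self.pressure(np.concatenate([A + eps, A - eps])))
        dP = P[: A.size] - P[A.size :]
        if np.any(dP == 0):
            raise ZeroDivisionError("singular compliance: flat tube law")
        out = 2.0 * eps / dP
        return float(out[0]) if scalar else out

    def wave_speed(self, A, rho: float):
        """Intrinsic wave speed c = sqrt(A / (rho * C_A)) in cm/s."""
        C = self.compliance(A)
        if np.any(np.asarray(C) <= 0):
            raise ValueError("non-positive compliance: wave speed undefined")
        return np.sqrt(np.asarray(A, dtype=float) / (rho * C))

    def pressure_and_compliance(self, A, eps: float = 1e-8):
        """(P(A), C_A(A)) in one stacked pressure evaluation.

        Time-stepping hot path: laws whose pressure is an expensive
        quadrature amortize per-call overhead by evaluating the central
        difference alongside the pressure in a single vectorized call.
        """
        A = np.asarray(A, dtype=float)
        stacked = np.concatenate([A, A + eps, A - eps])
        P = np.asarray(self.pressure(stacked))
        n = A.size
        dP = P[n : 2 * n] - P[2 * n :]
        if np.any(dP == 0):
            raise ZeroDivisionError("singular compliance: flat tube law")
        return P[:n], 2.0 * eps / dP


@dataclass(frozen=True)
class LinearTubeLawParams:
    """Parameters of the linear-in-radius tube law."""

    beta: float  # elasticity coefficient, dyn/cm^3
    A_ref: float  # reference area, cm^2
    P_ref: float = 0.0  # transmural pressure at A_ref, dyn/cm^2

    def __post_init__(self):
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.A_ref <= 0:
            raise ValueError("A_ref must be positive")


class LinearTubeLaw(TubeLaw):
    """P = P_ref + beta*(sqrt(A) - sqrt(A_ref)); compliance 2*sqrt(A)/beta."""

    def __init__(self, params: LinearTubeLawParams, p_ext: float = 0.0):
        self.params = params
        self.p_ext = p_ext

    def pressure(self, A):
        A = np.asarray(A, dtype=float)
        if np.any(A <= 0):
            raise ValueError("area must be positive")
        p = self.params
        return p.P_ref + p.beta * (np.sqrt(A) - np.sqrt(p.A_ref))

    def compliance(self, A, eps: float = 1e-8):  # closed form, eps unused
        A = np.asarray(A, dtype=float)
        return 2.0 * np.sqrt(A) / self.params.beta

    def pressure_and_compliance(self, A, eps: float = 1e-8):
        return self.pressure(A), self.compliance(A)

    def area_from_pressure(self, P):
        """Closed-form inverse; valid for P > P_ref - beta*sqrt(A_ref)."""
        p = self.params
        s = np.sqrt(p.A_ref) + (np.asarray(P, dtype=float) - p.P_ref) / p.beta
        if np.any(s <= 0):
            raise ValueError("pressure below the collapse limit of the linear law")
        return s**2


@dataclass(frozen=True)
class CalibrationResult:
    """Linear-law coefficients calibrated against a nonlinear source law."""

    beta_d: float  # from compliance at diastole
    beta_a: float  # from range-averaged compliance
    A_d: float  # diastolic area used as anchor (cm^2)
    P_d: float  # source transmural pressure at A_d (anchor P_ref)
    C_Ad: float  # source compliance at A_d
    C_Aa: float  # source compliance averaged over [A_d, A_s]

    def law(self, which: str, p_ext: float = 0.0) -> LinearTubeLaw:
        beta = {"beta_d": self.beta_d, "beta_a": self.beta_a}[which]
        return LinearTubeLaw(
            LinearTubeLawParams(beta=beta, A_ref=self.A_d, P_ref=self.P_d),
            p_ext=p_ext,
        )


def calibrate_linear(
    source: TubeLaw, A_d: float, A_s: float, n_avg: int = 101
) -> CalibrationResult:
    """Calibrate beta_d and beta_a from a source (hyperelastic) tube law.

    beta_d = 2*sqrt(A_d)/C_A(A_d); beta_a = 2*sqrt(A_d)/C_Aa where C_Aa is
    the trapezoidal mean of C_A on a uniform ``n_avg``-point grid over
    [A_d, A_s]. Both laws are anchored at the source diastolic point
    (A_ref, P_ref) = (A_d, P(A_d)), so they agree with the source at
    diastole exactly.
    """
    if A_s <= A_d:
        raise ValueError("require A_d < A_s for calibration")
    C_Ad = float(source.compliance(np.asarray([A_d]))[0])
    grid = np.linspace(A_d, A_s, n_avg)
    C_grid = np.asarray(source.compliance(grid), dtype=float)
    C_Aa = float(np.trapezoid(C_grid, grid) / (A_s - A_d))
    P_d = float(np.asarray(source.pressure(np.asarray([A_d])))[0])
    return CalibrationResult(
        beta_d=2.0 * np.sqrt(A_d) / C_Ad,
        beta_a=2.0 * np.sqrt(A_d) / C_Aa,
        A_d=A_d,
        P_d=P_d,
        C_Ad=C_Ad,
        C_Aa=C_Aa,
    )
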