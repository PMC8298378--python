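"""Boundary conditions: prescribed periodic inflow and the three-element
Windkessel outflow.

The inlet prescribes a periodic volumetric flow waveform Q_in(t); the
downstream vasculature is lumped into a proximal resistance R1, a
compliance C and a distal resistance R2 discharging to a reference
pressure P_out. The Windkessel capacitor ODE is discretized with the same
backward-difference scheme as the 1D solver and eliminated into the global
system, so the outlet closure is a linear relation P = a*Q + b at each
time step.

A parametric generator (:func:`synth_inflow`) builds a smooth resting-CCA
style waveform — a raised-cosine systolic pulse on a diastolic baseline —
from its period, mean flow, peak flow and systolic fraction. The packaged
default boundary conditions are synthetic: they are produced by this
generator with Windkessel coefficients calibrated once so the reference
carotid wall operates at its resting pressures (diastole near 79 mmHg,
systole near 130 mmHg).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import simpson
from scipy.interpolate import PchipInterpolator


@dataclass(frozen=True)
class WindkesselParams:
    """Three-element Windkessel (CGS: dyn*s/cm^5, cm^5/dyn, dyn/cm^2)."""

    R1: float  # proximal (characteristic) resistance
    C: float  # compliance
    R2: float  # distal resistance
    P_out: float = 0.0  # distal reference pressure

    def __post_init__(self):
        if self.R1 <= 0 or self.R2 <= 0 or self.C <= 0:
            raise ValueError("R1, C and R2 must be positive")
        if self.P_out < 0:
            raise ValueError("P_out must be non-negative")


class InflowWaveform:
    """Periodic volumetric inflow built from (t, Q) samples over one period.

    Interpolation is shape-preserving monotone cubic (PCHIP) on the
    periodically extended samples, so Q(t) = Q(t + T) and the interpolant
    is continuous across the period seam.
    """

    def __init__(self, t: np.ndarray, q: np.ndarray, period: float):
        t = np.asarray(t, dtype=float)
        q = np.asarray(q, dtype=float)
        if period <= 0:
            raise ValueError("period must be positive")
        if t.ndim != 1 or t.shape != q.shape or t.size < 4:
            raise ValueError("need matching 1D t, Q samples (>= 4 points)")
        if np.any(np.diff(t) <= 0) or t[0] < 0 or t[-1] > period:
            raise ValueError("sample times must increase within [0, period]")
        self.period = float(period)
        # close the period seam; drop a duplicated endpoint if present
        if np.isclose(t[-1], period):
            t, q = t[:-1], q[:-1]
        self.t = t
        self.q = q
        text = np.concatenate([t - period, t, t + period])
        qext = np.concatenate([q, q, q])
        self._interp = PchipInterpolator(text, qext)

    def __call__(self, t):
        return self._interp(np.mod(t, self.period))

    @property
    def mean(self) -> float:
        """Cycle-averaged flow (cm^3/s)."""
        tt = np.linspace(0.0, self.period, 2001)
        return float(simpson(self(tt), x=tt) / self.period)

    def scaled(self, factor: float) -> "InflowWaveform":
        """Pointwise-scaled copy (e.g. factor 1.30 for increased flow)."""
        return InflowWaveform(self.t.copy(), self.q * factor, self.period)

    def to_csv(self, path):
        """Write two-column CSV ``t,Q`` (s, ml/s)."""
        np.savetxt(
            path,
            np.column_stack([self.t, self.q]),
            delimiter=",",
            header="t,Q",
            comments="",
        )

    @classmethod
    def from_csv(cls, path, period: float | None = None) -> "InflowWaveform":
        data = np.loadtxt(path, delimiter=",", skiprows=1)
        t, q = data[:, 0], data[:, 1]
        if period is None:
            period = float(t[-1])
        return cls(t, q, period)


def synth_inflow(
    mean_q: float,
    peak_q: float,
    period: float,
    systolic_fraction: float = 0.3,
    n_samples: int = 401,
) -> InflowWaveform:
    """Parametric resting-CCA style inflow.

    Q(t) = Q_base + (peak_q - Q_base) * (1 - cos(2*pi*t/t_sys))/2 during
    systole (t < t_sys = systolic_fraction*period), Q_base in diastole.
    The baseline is chosen so the cycle mean equals ``mean_q``.
    """
    if not 0.0 < systolic_fraction < 1.0:
        raise ValueError("systolic_fraction must lie in (0, 1)")
    if not peak_q > mean_q > 0.0:
        raise ValueError("require peak_q > mean_q > 0")
    sf = systolic_fraction
    q_base = (mean_q - peak_q * sf / 2.0) / (1.0 - sf / 2.0)
    if q_base < 0:
        raise ValueError(
            "inconsistent parameters: requested mean implies negative "
            "diastolic baseline (reduce peak_q or systolic_fraction)"
        )
    t = np.linspace(0.0, period, n_samples)
    t_sys = sf * period
    q = np.where(
        t < t_sys,
        q_base + (peak_q - q_base) * 0.5 * (1.0 - np.cos(2 * np.pi * t / t_sys)),
        q_base,
    )
    return InflowWaveform(t, q, period)


def windkessel_closure(
    params: WindkesselParams,
    dt: float,
    bdf: tuple,
    p_c_hist: tuple,
):
    """Linear outlet closure coefficients for the current time step.

    The capacitor ODE C*dP_c/dt = Q - (P_c - P_out)/R2 discretized with
    backward-difference weights ``bdf = (a0, a1, a2)`` (applied to
    t^{n+1}, t^n, t^{n-1} and divided by dt) eliminates P_c^{n+1} into

        P_c^{n+1} = a_wk * Q^{n+1} + b_wk,

    so the outlet pressure satisfies P^{n+1} = (a_wk + R1)*Q^{n+1} + b_wk.
    Returns ``(a_wk, b_wk)``; after the global solve the new capacitor
    state is ``a_wk*Q + b_wk``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    a0, a1, a2 = bdf
    p_c_n, p_c_nm1 = p_c_hist
    denom = params.C * a0 / dt + 1.0 / params.R2
    a_wk = 1.0 / denom
    b_wk = (
        params.P_out / params.R2
        - params.C * (a1 * p_c_n + a2 * p_c_nm1) / dt
    ) * a_wk
    return a_wk, b_wk


def windkessel_step(
    p_c: float,
    q_out: float,
    dt: float,
    params: WindkesselParams,
    p_c_prev: float | None = None,
):
    """One backward-difference update of the capacitor pressure given the
    outlet flow. Uses BDF2 when ``p_c_prev`` is supplied, else backward
    Euler. Returns ``((a_wk, b_wk), p_c_new)``.
    """
    if p_c_prev is None:
        bdf = (1.0, -1.0, 0.0)
        p_c_prev = p_c
    else:
        bdf = (1.5, -2.0, 0.5)
    a_wk, b_wk = windkessel_closure(params, dt, bdf, (p_c, p_c_prev))
    return (a_wk, b_wk), a_wk * q_out + b_wk
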