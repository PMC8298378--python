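"""Haemodynamic indices: systolic/diastolic extraction, distensibility,
Bramwell-Hill PWV and foot-to-foot PWV.

Distensibility D = (A_s - A_d)/(A_d * (P_s - P_d)) is the clinical
stiffness metric; the Bramwell-Hill relation PWV_BH = 1/sqrt(rho*D)
converts it into an equivalent pulse wave velocity. The foot-to-foot PWV
is the transit speed of the diastolic foot of the pressure waveform
between two axial sites; with a coarse solver time grid the foot instant
is refined by parabolic interpolation through the discrete minimum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .solver import HaemoState
from .units import MMHG, cms_to_ms
from .wall import FluidProperties

__all__ = [
    "HaemodynamicSummary",
    "extract_extrema",
    "distensibility",
    "pwv_bramwell_hill",
    "pwv_foot_to_foot",
    "summarize",
]


@dataclass(frozen=True)
class HaemodynamicSummary:
    """One row of cycle metrics at a recording site (I/O units: mmHg,
    cm^2, m/s, 1/mmHg)."""

    PWV_foot: float  # m/s
    P_s: float  # mmHg
    P_d: float  # mmHg
    A_s: float  # cm^2
    A_d: float  # cm^2
    D: float  # 1/mmHg
    PWV_BH: float  # m/s
    recording_z: float  # cm

    @property
    def dP(self) -> float:
        return self.P_s - self.P_d

    @property
    def dA(self) -> float:
        return self.A_s - self.A_d

    def as_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "PWV_foot", "P_s", "P_d", "A_s", "A_d", "D", "PWV_BH",
            "recording_z")}
        d["dP"], d["dA"] = self.dP, self.dA
        return d


def _parabolic_vertex(y0: float, y1: float, y2: float):
    """Vertex (offset in samples from the middle point, value) of the
    parabola through three equispaced samples."""
    denom = y0 - 2.0 * y1 + y2
    if denom == 0.0:
        return 0.0, y1
    delta = 0.5 * (y0 - y2) / denom
    value = y1 - 0.25 * (y0 - y2) * delta
    return delta, value


def _refined_extremum(t: np.ndarray, y: np.ndarray, kind: str):
    """(time, value) of the cycle extremum with parabolic sub-sample
    refinement; the trace is treated as periodic (endpoints identified)."""
    yy = y[:-1] if np.isclose(y[0], y[-1], rtol=0, atol=abs(y[0]) * 1e-9 + 1e-12) else y
    n = len(yy)
    i = int(np.argmax(yy)) if kind == "max" else int(np.argmin(yy))
    dt = t[1] - t[0]
    y0, y1, y2 = yy[(i - 1) % n], yy[i], yy[(i + 1) % n]
    delta, value = _parabolic_vertex(y0, y1, y2)
    delta = float(np.clip(delta, -0.5, 0.5))
    return t[0] + ((i + delta) % n) * dt, value


def extract_extrema(t, P, A, periodicity_residual: float | None = None):
    """Systolic/diastolic pressure and area over one periodic cycle at a
    fixed site, with parabolic sub-sample refinement of each extremum.

    Returns ``(P_s, P_d, A_s, A_d)`` in the units of the inputs. If a
    periodicity residual is supplied and exceeds 0.5 mmHg, a warning is
    emitted (the cycle is not converged to a periodic orbit).
    """
    t = np.asarray(t, dtype=float)
    P = np.asarray(P, dtype=float)
    A = np.asarray(A, dtype=float)
    if periodicity_residual is not None and np.isfinite(periodicity_residual):
        if periodicity_residual > 0.5 * MMHG:
            warnings.warn(
                "cycle not periodic: residual "
                f"{periodicity_residual / MMHG:.3f} mmHg", stacklevel=2,
            )
    _, P_s = _refined_extremum(t, P, "max")
    _, P_d = _refined_extremum(t, P, "min")
    _, A_s = _refined_extremum(t, A, "max")
    _, A_d = _refined_extremum(t, A, "min")
    return P_s, P_d, A_s, A_d


def distensibility(P_s, P_d, A_s, A_d):
    """D = (A_s - A_d)/(A_d * (P_s - P_d)), in 1/(pressure unit of P)."""
    dP = P_s - P_d
    if dP == 0:
        raise ZeroDivisionError("zero pulse pressure")
    return (A_s - A_d) / (A_d * dP)


def pwv_bramwell_hill(D_per_mmhg: float, fluid: FluidProperties) -> float:
    """PWV_BH = 1/sqrt(rho*D) in m/s, with D given in 1/mmHg."""
    if D_per_mmhg <= 0:
        raise ValueError("distensibility must be positive")
    D_cgs = D_per_mmhg / MMHG  # 1/mmHg -> cm^2/dyn
    return cms_to_ms(1.0 / np.sqrt(fluid.rho * D_cgs))


def foot_time(t: np.ndarray, p: np.ndarray, method: str = "minimum") -> float:
    """Foot instant of a periodic pressure trace.

    ``minimum`` (default): time of the cycle minimum, parabolic refined.
    ``tangent``: intersecting-tangent method — crossing of the horizontal
    through the minimum with the tangent at the steepest systolic upstroke.
    """
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    if method == "minimum":
        tf, _ = _refined_extremum(t, p, "min")
        return tf
    if method == "tangent":
        t_min, p_min = _refined_extremum(t, p, "min")
        dpdt = np.gradient(p, t)
        i = int(np.argmax(dpdt))
        return t[i] - (p[i] - p_min) / dpdt[i]
    raise ValueError(f"unknown foot method {method!r}")


def pwv_foot_to_foot(
    t,
    p_site1,
    p_site2,
    distance: float,
    period: float | None = None,
    method: str = "minimum",
) -> float:
    """PWV = distance / (t_foot2 - t_foot1), reported in m/s.

    The two traces must be synchronized periodic cycles; ``distance`` is
    the axial separation of the sites in cm. If the raw foot delay is
    non-positive it is unwrapped by one period; a persistently
    non-positive delay raises (sites likely swapped).
    """
    if distance <= 0:
        raise ValueError("distance must be positive")
    t = np.asarray(t, dtype=float)
    if period is None:
        period = float(t[-1] - t[0])
    tf1 = foot_time(t, np.asarray(p_site1, dtype=float), method)
    tf2 = foot_time(t, np.asarray(p_site2, dtype=float), method)
    delay = (tf2 - tf1) % period
    if delay > period / 2.0:
        delay -= period
    if delay <= 0:
        raise ValueError(
            f"non-positive foot delay ({delay * 1e3:.2f} ms): check site "
            "ordering (site1 must be upstream)"
        )
    return cms_to_ms(distance / delay)


def summarize(
    state: HaemoState,
    fluid: FluidProperties,
    site: int | None = None,
    pwv_sites: tuple = (0, -1),
    foot_method: str = "tangent",
) -> HaemodynamicSummary:
    """Condense a converged cycle into the standard metric row.

    Extrema and distensibility are taken at ``site`` (default: the mid
    node, z = l/2); foot-to-foot PWV between ``pwv_sites`` (default inlet
    and outlet, i.e. the full fluid length).
    """
    if site is None:
        site = state.P.shape[0] // 2
    P_s, P_d, A_s, A_d = extract_extrema(
        state.t, state.P[site], state.A[site],
        periodicity_residual=state.periodicity_residual,
    )
    i1, i2 = pwv_sites
    dist = abs(state.z[i2] - state.z[i1])
    pwv = pwv_foot_to_foot(
        state.t, state.P[i1], state.P[i2], dist,
        period=state.period, method=foot_method,
    )
    D = distensibility(P_s / MMHG, P_d / MMHG, A_s, A_d)  # 1/mmHg
    return HaemodynamicSummary(
        PWV_foot=pwv,
        P_s=P_s / MMHG,
        P_d=P_d / MMHG,
        A_s=A_s,
        A_d=A_d,
        D=D,
        PWV_BH=pwv_bramwell_hill(D, fluid),
        recording_z=float(state.z[site]),
    )
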