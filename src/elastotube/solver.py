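"""Implicit 1D blood-flow solver closed by an arbitrary tube law.

Mass and momentum conservation for pressure P and flow Q on a single
compliant segment,

    C_A dP/dt + dQ/dz = 0
    (rho/A) dQ/dt + dP/dz = -[(rho/A) d(Q^2/A)/dz + 8*pi*mu*Q/A^2],

are integrated element-wise with the trapezoidal rule in space and a
second-order backward difference in time (first step of a run, and the
first step after a time-step change, fall back to backward Euler). The
convection and Poiseuille-friction terms on the right-hand side are
evaluated explicitly at the previous time level, as is the compliance, so
each step is one sparse linear solve in the 2N nodal unknowns (P, Q).
After the solve, nodal areas are recovered from the tube law by the
compliance-preconditioned secant iteration, and the nodal compliances are
refreshed by central finite difference.

The time step is adaptive: dt = CFL * l_e / c_max with CFL ~ 2.5, held
fixed within a cardiac cycle and recomputed between cycles from the
previous cycle's maximum intrinsic wave speed (rounded so an integer
number of steps tiles the period).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .boundaries import InflowWaveform, WindkesselParams, windkessel_closure
from .tube_laws import TubeLaw
from .units import MMHG
from .wall import FluidProperties

logger = logging.getLogger(__name__)

_BDF1 = (1.0, -1.0, 0.0)
_BDF2 = (1.5, -2.0, 0.5)


@dataclass(frozen=True)
class VesselMesh:
    """Uniform 1D mesh of the fluid domain."""

    length: float  # cm
    n_elements: int = 14

    def __post_init__(self):
        if self.length <= 0:
            raise ValueError("length must be positive")
        if self.n_elements < 2:
            raise ValueError("need at least 2 elements")

    @property
    def l_e(self) -> float:
        return self.length / self.n_elements

    @property
    def n_nodes(self) -> int:
        return self.n_elements + 1

    @property
    def node_z(self) -> np.ndarray:
        return np.linspace(0.0, self.length, self.n_nodes)


@dataclass
class HaemoState:
    """Pressure/flow/area fields of one cardiac cycle on (node x time)."""

    t: np.ndarray  # s, relative to cycle start, both endpoints included
    z: np.ndarray  # axial node coordinates, cm
    P: np.ndarray  # dyn/cm^2, (n_nodes, n_t)
    Q: np.ndarray  # cm^3/s
    A: np.ndarray  # cm^2
    cycle_index: int = 0
    periodicity_residual: float = np.nan  # max|P - P_prev_cycle|, dyn/cm^2

    @property
    def period(self) -> float:
        return float(self.t[-1] - self.t[0])


@dataclass
class SimulationConfig:
    """Complete description of one run."""

    tube_law: TubeLaw
    mesh: VesselMesh
    fluid: FluidProperties
    inflow: InflowWaveform
    windkessel: WindkesselParams
    n_cycles: int = 10
    cfl: float = 2.5
    p_init: float = 80.0 * MMHG  # uniform initial pressure, dyn/cm^2
    secant_tol: float = 1e-6  # area residual, cm^2
    secant_max_iter: int = 100
    store_all_cycles: bool = False


@dataclass
class CycleLog:
    """Per-cycle convergence diagnostics."""

    dt: list = field(default_factory=list)
    c_max: list = field(default_factory=list)
    cfl_realized: list = field(default_factory=list)
    periodicity_residual: list = field(default_factory=list)


def update_area_secant(
    P_target,
    A_guess,
    tube_law: TubeLaw,
    tol: float = 1e-6,
    max_iter: int = 100,
):
    """Recover lumen area from luminal pressure through the tube law.

    Iterates A <- A + (P_target - P_ext - Pbar(A)) * C_A(A) until the
    area update falls below ``tol`` (cm^2). Vectorized over nodes. The
    compliance acts as a local secant slope, so convergence is
    Newton-like for smooth laws.
    """
    A = np.atleast_1d(np.asarray(A_guess, dtype=float)).copy()
    P_target = np.broadcast_to(
        np.asarray(P_target, dtype=float), A.shape
    ).astype(float)
    for it in range(max_iter):
        Pbar, C = tube_law.pressure_and_compliance(A)
        dA = (P_target - tube_law.p_ext - Pbar) * C
        A_new = A + dA
        if np.any(A_new <= 0):
            raise FloatingPointError(
                "secant area update produced non-positive area"
            )
        step = float(np.max(np.abs(A_new - A)))
        A = A_new
        if step < tol:
            break
        if it == 49:
            logger.warning("secant area update slow: 50 iterations, "
                           "residual %.3e cm^2", step)
    else:
        raise RuntimeError(
            f"secant area update failed to converge in {max_iter} "
            f"iterations; last residual {step:.3e} cm^2"
        )
    return A if np.ndim(A_guess) else float(A[0])


def adaptive_timestep(c_max: float, l_e: float, cfl: float = 2.5) -> float:
    """dt = CFL * l_e / c_max."""
    if c_max <= 0:
        raise ValueError("wave speed must be positive")
    return cfl * l_e / c_max


def _assemble_and_solve(
    P_n, Q_n, P_nm1, Q_nm1, A_n, C_n,
    cfg: SimulationConfig,
    t_new: float,
    dt: float,
    bdf: tuple,
    wk_coeffs: tuple,
):
    """One implicit step: build the 2N x 2N system and solve for
    (P, Q) at the new time level."""
    mesh, fluid = cfg.mesh, cfg.fluid
    N = mesh.n_nodes
    le = mesh.l_e
    a0, a1, a2 = bdf
    z = mesh.node_z

    # explicit convection + friction source at time n (per node)
    conv = np.gradient(Q_n**2 / A_n, z)
    s = -(fluid.rho / A_n) * conv - 8.0 * np.pi * fluid.mu * Q_n / A_n**2

    M = np.zeros((2 * N, 2 * N))
    rhs = np.zeros(2 * N)
    jj = np.arange(N - 1)

    # mass rows (one per element): indices 0..N-2
    cP = 0.5 * le * C_n * a0 / dt  # nodal coefficient on P^{n+1}
    hist_P = 0.5 * le * C_n * (a1 * P_n + a2 * P_nm1) / dt
    M[jj, jj] += cP[:-1]
    M[jj, jj + 1] += cP[1:]
    M[jj, N + jj] += -1.0
    M[jj, N + jj + 1] += 1.0
    rhs[jj] = -(hist_P[:-1] + hist_P[1:])

    # momentum rows: indices N-1 .. 2N-3
    mm = (N - 1) + jj
    cQ = 0.5 * le * (fluid.rho / A_n) * a0 / dt
    hist_Q = 0.5 * le * (fluid.rho / A_n) * (a1 * Q_n + a2 * Q_nm1) / dt
    M[mm, N + jj] += cQ[:-1]
    M[mm, N + jj + 1] += cQ[1:]
    M[mm, jj] += -1.0
    M[mm, jj + 1] += 1.0
    rhs[mm] = 0.5 * le * (s[:-1] + s[1:]) - (hist_Q[:-1] + hist_Q[1:])

    # inlet: prescribed flow
    M[2 * N - 2, N] = 1.0
    rhs[2 * N - 2] = cfg.inflow(t_new)

    # outlet: Windkessel closure P - (a_wk + R1) Q = b_wk
    a_wk, b_wk = wk_coeffs
    M[2 * N - 1, N - 1] = 1.0
    M[2 * N - 1, 2 * N - 1] = -(a_wk + cfg.windkessel.R1)
    rhs[2 * N - 1] = b_wk

    try:
        x = np.linalg.solve(M, rhs)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise RuntimeError(
            f"singular global system at t={t_new:.4f} s "
            f"(dt={dt:.3e}, bdf={bdf})"
        ) from exc
    return x[:N], x[N:]


def run_simulation(cfg: SimulationConfig):
    """Advance ``cfg.n_cycles`` cardiac cycles and return
    ``(HaemoState, CycleLog)`` for the final cycle.

    The returned state carries the periodicity residual (max-norm pressure
    difference between the last two cycles). Divergence (NaN or
    non-positive area) aborts with cycle/time diagnostics.
    """
    law, mesh, fluid = cfg.tube_law, cfg.mesh, cfg.fluid
    T = cfg.inflow.period
    N = mesh.n_nodes

    # initial state: uniform pressure, zero flow, consistent area
    P = np.full(N, cfg.p_init)
    if hasattr(law, "wall"):
        A0 = np.pi * law.wall.R_i**2
    elif hasattr(law, "params"):
        A0 = law.params.A_ref
    else:  # pragma: no cover - exotic custom laws
        A0 = 1.0
    A0_guess = np.full(N, A0)
    A = update_area_secant(P, A0_guess, law,
                           tol=cfg.secant_tol, max_iter=cfg.secant_max_iter)
    C = np.asarray(law.compliance(A))
    Q = np.zeros(N)
    P_prev, Q_prev = P.copy(), Q.copy()

    p_c = float(cfg.p_init - cfg.windkessel.R1 * cfg.inflow(0.0))
    p_c_prev = p_c

    c_max = float(np.max(np.sqrt(A / (fluid.rho * C))))
    log = CycleLog()
    prev_cycle_P = None
    state = None
    all_states = []

    for cyc in range(cfg.n_cycles):
        dt_raw = adaptive_timestep(c_max, mesh.l_e, cfg.cfl)
        n_steps = max(int(np.ceil(T / dt_raw)), 4)
        dt = T / n_steps
        dt_changed = cyc == 0 or not np.isclose(dt, log.dt[-1])
        log.dt.append(dt)

        P_hist = np.empty((N, n_steps + 1))
        Q_hist = np.empty((N, n_steps + 1))
        A_hist = np.empty((N, n_steps + 1))
        P_hist[:, 0], Q_hist[:, 0], A_hist[:, 0] = P, Q, A
        c_cycle = float(np.max(np.sqrt(A / (fluid.rho * C))))

        for i in range(n_steps):
            t_new = cyc * T + (i + 1) * dt
            bdf = _BDF1 if (dt_changed and i == 0) else _BDF2
            wk = windkessel_closure(
                cfg.windkessel, dt, bdf, (p_c, p_c_prev)
            )
            P_new, Q_new = _assemble_and_solve(
                P, Q, P_prev, Q_prev, A, C, cfg, t_new, dt, bdf, wk
            )
            if not np.all(np.isfinite(P_new)) or not np.all(np.isfinite(Q_new)):
                raise RuntimeError(
                    f"solver diverged at cycle {cyc + 1}, t={t_new:.4f} s"
                )
            A_new = update_area_secant(
                P_new, A, law, tol=cfg.secant_tol,
                max_iter=cfg.secant_max_iter,
            )
            if np.any(A_new <= 0):
                raise RuntimeError(
                    f"non-positive area at cycle {cyc + 1}, t={t_new:.4f} s"
                )
            p_c_new = wk[0] * Q_new[-1] + wk[1]

            P_prev, Q_prev = P, Q
            P, Q, A = P_new, Q_new, np.asarray(A_new)
            C = np.asarray(law.compliance(A))
            p_c_prev, p_c = p_c, p_c_new

            c_now = float(np.max(np.sqrt(A / (fluid.rho * C))))
            c_cycle = max(c_cycle, c_now)
            P_hist[:, i + 1], Q_hist[:, i + 1], A_hist[:, i + 1] = P, Q, A

        c_max = c_cycle
        log.c_max.append(c_max)
        log.cfl_realized.append(c_max * dt / mesh.l_e)
        if prev_cycle_P is not None and prev_cycle_P.shape == P_hist.shape:
            resid = float(np.max(np.abs(P_hist - prev_cycle_P)))
        else:
            resid = np.nan
        log.periodicity_residual.append(resid)
        logger.info(
            "cycle %d/%d: dt=%.4e s, CFL=%.2f, periodicity residual=%s mmHg",
            cyc + 1, cfg.n_cycles, dt, log.cfl_realized[-1],
            f"{resid / MMHG:.4f}" if np.isfinite(resid) else "n/a",
        )
        prev_cycle_P = P_hist
        state = HaemoState(
            t=np.linspace(0.0, T, n_steps + 1),
            z=mesh.node_z,
            P=P_hist, Q=Q_hist, A=A_hist,
            cycle_index=cyc,
            periodicity_residual=resid,
        )
        if cfg.store_all_cycles:
            all_states.append(state)

    if cfg.store_all_cycles:
        return all_states, log
    return state, log


def mass_balance_error(state: HaemoState) -> float:
    """|net inflow - net outflow| over the cycle, as a fraction of the
    stroke volume (the cycle-integrated inflow)."""
    from scipy.integrate import simpson

    vin = simpson(state.Q[0], x=state.t)
    vout = simpson(state.Q[-1], x=state.t)
    return abs(vin - vout) / abs(vin)
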