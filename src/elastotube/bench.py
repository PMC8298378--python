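"""Virtual-experiment bench: biaxial tests, in-vivo stretch identification,
scenario fixtures and tube-law comparison reports.

The two laboratory protocols used to characterize arterial segments are
reproduced numerically on the hyperelastic wall:

* pressure–diameter test: inflate at fixed vessel length (constant axial
  stretch), record outer radius and reduced axial force;
* force–length test: stretch axially at constant luminal pressure.

Arteries at their in-vivo axial stretch show a flat axial-force/pressure
relationship; :func:`find_invivo_stretch` exploits this to identify the
physiological stretch by minimizing the force spread over a pressure
range (default 10–200 mmHg).

Scenario fixtures provide the reference carotid and the three virtual
arteries VA1–VA3 (stress-free inner radius and opening angle at 80%, 90%
and 110% of the reference, all other parameters unchanged), and
:func:`run_scenario` performs the full tube-law comparison: a hyperelastic
run, diastole- and average-compliance linear-law runs calibrated from it,
optionally repeated with the inflow raised 30% (without recalibrating the
linear laws), reporting percentage errors e(X) = 100*(X_linear -
X_hyperelastic)/X_hyperelastic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .boundaries import InflowWaveform, WindkesselParams, synth_inflow
from .indices import HaemodynamicSummary, summarize
from .solver import SimulationConfig, VesselMesh, run_simulation
from .tube_laws import CalibrationResult, TubeLaw, calibrate_linear
from .units import MMHG
from .wall import (
    FluidProperties,
    HyperelasticTubeLaw,
    WallParameters,
    axial_force,
    deformed_radius,
)

logger = logging.getLogger(__name__)

__all__ = [
    "BiaxialCurve",
    "ScenarioFixture",
    "pressure_diameter_test",
    "force_length_test",
    "find_invivo_stretch",
    "reference_bcs",
    "virtual_artery",
    "scenario_fixture",
    "simulate_wall",
    "run_scenario",
]


@dataclass
class BiaxialCurve:
    """Response of one virtual biaxial experiment."""

    control: np.ndarray  # pressure (dyn/cm^2) or axial stretch grid
    control_name: str
    r_o: np.ndarray  # loaded outer radius, cm
    F_z: np.ndarray  # reduced axial force, dyn
    A: np.ndarray  # lumen area, cm^2
    truncated: bool = False

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {self.control_name: self.control, "r_o": self.r_o,
             "F_z": self.F_z, "A": self.A}
        )


def pressure_diameter_test(
    wall: WallParameters,
    lambda_z: float | None = None,
    P_grid=None,
    quad_n: int = 21,
) -> BiaxialCurve:
    """Inflation at fixed vessel length: solve the tube law at each
    pressure of ``P_grid`` (dyn/cm^2, increasing), recording outer radius
    and axial force. Unattainable pressures truncate the curve with a
    warning."""
    if lambda_z is not None:
        wall = wall.replace(lambda_z=lambda_z)
    if P_grid is None:
        P_grid = np.linspace(10.0, 200.0, 39) * MMHG
    P_grid = np.asarray(P_grid, dtype=float)
    if np.any(np.diff(P_grid) <= 0):
        raise ValueError("P_grid must be strictly increasing")
    law = HyperelasticTubeLaw(wall, quad_n=quad_n)
    r_o, F_z, A, P_kept = [], [], [], []
    truncated = False
    for P in P_grid:
        try:
            a = law.area_from_pressure(P)
        except ValueError:
            truncated = True
            logger.warning(
                "pressure %.1f mmHg outside attainable range; curve "
                "truncated", P / MMHG,
            )
            break
        r_i = math.sqrt(a / math.pi)
        r_o.append(float(deformed_radius(wall.R_i + wall.H, r_i, wall)))
        F_z.append(axial_force(r_i, wall, quad_n=quad_n))
        A.append(a)
        P_kept.append(P)
    return BiaxialCurve(
        control=np.asarray(P_kept), control_name="P",
        r_o=np.asarray(r_o), F_z=np.asarray(F_z), A=np.asarray(A),
        truncated=truncated,
    )


def force_length_test(
    wall: WallParameters,
    P: float,
    lambda_z_grid,
    quad_n: int = 21,
) -> BiaxialCurve:
    """Axial extension at constant luminal pressure ``P`` (dyn/cm^2):
    solve the tube law for each stretch of ``lambda_z_grid``."""
    lz_grid = np.atleast_1d(np.asarray(lambda_z_grid, dtype=float))
    if np.any(lz_grid <= 1.0) or np.any(lz_grid >= 2.0):
        raise ValueError("axial stretches must lie in (1, 2)")
    r_o, F_z, A = [], [], []
    for lz in lz_grid:
        w = wall.replace(lambda_z=float(lz))
        law = HyperelasticTubeLaw(w, quad_n=quad_n)
        a = law.area_from_pressure(P)
        r_i = math.sqrt(a / math.pi)
        r_o.append(float(deformed_radius(w.R_i + w.H, r_i, w)))
        F_z.append(axial_force(r_i, w, quad_n=quad_n))
        A.append(a)
    return BiaxialCurve(
        control=lz_grid, control_name="lambda_z",
        r_o=np.asarray(r_o), F_z=np.asarray(F_z), A=np.asarray(A),
    )


def find_invivo_stretch(
    wall: WallParameters,
    lambda_z_grid=(1.2, 1.3, 1.4, 1.5),
    p_range=(10.0 * MMHG, 200.0 * MMHG),
    n_p: int = 20,
    quad_n: int = 21,
):
    """Identify the in-vivo axial stretch as the grid value minimizing the
    spread (max - min) of axial force over the pressure range.

    Returns ``(lambda_z_star, spreads)`` where ``spreads`` maps each grid
    stretch to its force spread in dyn. Ties resolve to the smallest
    stretch with a warning.
    """
    lz_grid = np.atleast_1d(np.asarray(lambda_z_grid, dtype=float))
    P_grid = np.linspace(p_range[0], p_range[1], n_p)
    spreads = {}
    for lz in lz_grid:
        curve = pressure_diameter_test(wall, float(lz), P_grid, quad_n=quad_n)
        spreads[float(lz)] = float(np.max(curve.F_z) - np.min(curve.F_z))
    vals = np.asarray(list(spreads.values()))
    i_min = int(np.argmin(vals))
    near = np.isclose(vals, vals[i_min], rtol=1e-9)
    if np.sum(near) > 1:
        logger.warning(
            "non-unique flat point: %d grid stretches tie; returning the "
            "smallest", int(np.sum(near)),
        )
        i_min = int(np.flatnonzero(near)[0])
    return float(lz_grid[i_min]), spreads


# --- scenario fixtures -------------------------------------------------

#: (stress-free inner radius cm, opening angle deg) of the virtual
#: arteries; R_i and omega at 80/90/110% of the reference carotid, all
#: other parameters unchanged
VA_GEOMETRY = {
    1: (0.3448, 64.72),
    2: (0.3879, 72.81),
    3: (0.4741, 88.99),
}


def virtual_artery(index: int, lambda_z: float = 1.4) -> WallParameters:
    """VA1, VA2 or VA3: the reference carotid with rescaled stress-free
    inner radius and opening angle."""
    R_i, omega_deg = VA_GEOMETRY[index]
    return WallParameters.sommer_cca(lambda_z=lambda_z).replace(
        R_i=R_i, omega=math.radians(omega_deg)
    )


def reference_bcs():
    """Packaged default boundary conditions (synthetic).

    A parametric resting-CCA inflow (period 1.1 s, mean 6.5 ml/s, peak
    21 ml/s, 30% systolic fraction) and three-element Windkessel
    coefficients, calibrated once against the reference carotid wall so
    the simulated operating point matches resting carotid pressures
    (diastole ~79 mmHg, systole ~130 mmHg).
    """
    inflow = synth_inflow(mean_q=6.5, peak_q=21.0, period=1.1,
                          systolic_fraction=0.3)
    wk = WindkesselParams(R1=2.5e3, C=4.6e-5, R2=1.72e4, P_out=0.0)
    return inflow, wk


@dataclass(frozen=True)
class ScenarioFixture:
    """One tube-law comparison scenario."""

    name: str
    wall: WallParameters
    increased_flow: bool = False  # also run the +30% inflow state
    tube_laws: tuple = ("hyperelastic", "beta_d", "beta_a")


def scenario_fixture(va: int | None = None, increased_flow: bool = False
                     ) -> ScenarioFixture:
    wall = virtual_artery(va) if va else WallParameters.sommer_cca()
    name = f"VA{va}" if va else "reference"
    return ScenarioFixture(name=name, wall=wall,
                           increased_flow=increased_flow)


def simulate_wall(
    wall: WallParameters,
    fluid: FluidProperties | None = None,
    inflow: InflowWaveform | None = None,
    windkessel: WindkesselParams | None = None,
    n_cycles: int = 10,
    n_elements: int = 14,
    quad_n: int = 21,
    use_stress_free_length: bool = False,
    tube_law: TubeLaw | None = None,
    foot_method: str = "tangent",
):
    """Run one simulation for a wall (or an explicit tube law) under the
    packaged default boundary conditions and summarize it.

    The fluid mesh spans the loaded length l = lambda_z*L by default;
    ``use_stress_free_length`` switches to the stress-free L. Returns
    ``(HaemodynamicSummary, HaemoState)``.
    """
    fluid = fluid or FluidProperties()
    if inflow is None or windkessel is None:
        d_inflow, d_wk = reference_bcs()
        inflow = inflow or d_inflow
        windkessel = windkessel or d_wk
    length = wall.L if use_stress_free_length else wall.loaded_length
    mesh = VesselMesh(length=length, n_elements=n_elements)
    law = tube_law or HyperelasticTubeLaw(wall, quad_n=quad_n)
    cfg = SimulationConfig(
        tube_law=law, mesh=mesh, fluid=fluid, inflow=inflow,
        windkessel=windkessel, n_cycles=n_cycles,
    )
    state, _ = run_simulation(cfg)
    return summarize(state, fluid, foot_method=foot_method), state


_ERR_COLS = ("PWV_foot", "P_s", "P_d", "A_s", "A_d")


def _errors(lin: HaemodynamicSummary, ref: HaemodynamicSummary) -> dict:
    """e(X)% = 100*(X_linear - X_hyperelastic)/X_hyperelastic."""
    return {
        f"e({c})%": 100.0 * (getattr(lin, c) - getattr(ref, c))
        / getattr(ref, c)
        for c in _ERR_COLS
    }


def run_scenario(
    fixture: ScenarioFixture,
    fluid: FluidProperties | None = None,
    inflow: InflowWaveform | None = None,
    windkessel: WindkesselParams | None = None,
    n_cycles: int = 10,
    n_elements: int = 14,
    flow_increase: float = 1.30,
    foot_method: str = "tangent",
):
    """Full tube-law comparison for one scenario.

    Runs the hyperelastic model under normal flow, calibrates the two
    linear laws from that run (diastolic and averaged compliance, anchored
    at the hyperelastic diastolic point), then runs each linear law under
    normal flow and, if requested, all three under the increased inflow —
    with the linear coefficients kept from the normal-flow calibration.

    Returns ``(summaries, errors, calibration)``: two DataFrames indexed
    by (flow state, tube law) and the :class:`CalibrationResult`.
    """
    fluid = fluid or FluidProperties()
    if inflow is None or windkessel is None:
        d_inflow, d_wk = reference_bcs()
        inflow = inflow or d_inflow
        windkessel = windkessel or d_wk

    common = dict(fluid=fluid, windkessel=windkessel, n_cycles=n_cycles,
                  n_elements=n_elements, foot_method=foot_method)
    states = {}
    summaries = {}
    ref, state = simulate_wall(fixture.wall, inflow=inflow, **common)
    summaries[("normal", "hyperelastic")] = ref
    states[("normal", "hyperelastic")] = state

    hyper_law = HyperelasticTubeLaw(fixture.wall)
    calib = calibrate_linear(hyper_law, A_d=ref.A_d, A_s=ref.A_s)
    logger.info("calibrated beta_d=%.4g, beta_a=%.4g dyn/cm^3 from "
                "A_d=%.4f, A_s=%.4f", calib.beta_d, calib.beta_a,
                ref.A_d, ref.A_s)

    flows = [("normal", inflow)]
    if fixture.increased_flow:
        flows.append(("increased", inflow.scaled(flow_increase)))

    for flow_name, q in flows:
        for law_name in fixture.tube_laws:
            if (flow_name, law_name) in summaries:
                continue
            law = (HyperelasticTubeLaw(fixture.wall)
                   if law_name == "hyperelastic" else calib.law(law_name))
            s, st = simulate_wall(fixture.wall, inflow=q, tube_law=law,
                                  **common)
            summaries[(flow_name, law_name)] = s
            states[(flow_name, law_name)] = st

    rows = {key: s.as_dict() for key, s in summaries.items()}
    summary_df = pd.DataFrame(rows).T
    summary_df.index.names = ["flow", "tube_law"]

    err_rows = {}
    for flow_name, _ in flows:
        cur = summaries[(flow_name, "hyperelastic")]
        for law_name in fixture.tube_laws:
            if law_name == "hyperelastic":
                continue
            err_rows[(flow_name, law_name)] = _errors(
                summaries[(flow_name, law_name)], cur
            )
    err_df = pd.DataFrame(err_rows).T
    if not err_df.empty:
        err_df.index.names = ["flow", "tube_law"]
    return summary_df, err_df, calib
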