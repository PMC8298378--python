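"""Shared fixtures.

Expensive transient simulations are session-scoped and shared across test
modules; everything is generated at run time (no stored data files).
"""

from __future__ import annotations

import numpy as np
import pytest

from elastotube.bench import (
    reference_bcs,
    run_scenario,
    scenario_fixture,
)
from elastotube.sensitivity import default_box, make_pwv_model, sobol_indices
from elastotube.solver import SimulationConfig, VesselMesh, run_simulation
from elastotube.wall import (
    FluidProperties,
    HyperelasticTubeLaw,
    WallParameters,
)


@pytest.fixture(scope="session")
def sommer_wall() -> WallParameters:
    return WallParameters.sommer_cca()


@pytest.fixture(scope="session")
def delfino_wall() -> WallParameters:
    return WallParameters.delfino_cca()


@pytest.fixture(scope="session")
def fluid() -> FluidProperties:
    return FluidProperties()


@pytest.fixture(scope="session")
def hyper_law(sommer_wall) -> HyperelasticTubeLaw:
    return HyperelasticTubeLaw(sommer_wall)


@pytest.fixture(scope="session")
def reference_run(sommer_wall, fluid):
    """Converged 10-cycle reference carotid run: (HaemoState, CycleLog)."""
    inflow, wk = reference_bcs()
    cfg = SimulationConfig(
        tube_law=HyperelasticTubeLaw(sommer_wall),
        mesh=VesselMesh(length=sommer_wall.loaded_length, n_elements=14),
        fluid=fluid,
        inflow=inflow,
        windkessel=wk,
        n_cycles=10,
    )
    return run_simulation(cfg)


@pytest.fixture(scope="session")
def va1_scenario():
    """Tube-law comparison for virtual artery 1 under normal flow:
    (summaries, errors, calibration)."""
    return run_scenario(scenario_fixture(va=1))


@pytest.fixture(scope="session")
def cca_sobol(sommer_wall, fluid):
    """Scaled-down dynamic Sobol analysis of the carotid PWV.

    Full transient model per evaluation at reduced problem size (4
    cycles, 10 elements, 11 radial quadrature nodes, n=8 per sample
    matrix); the ranking of the dominant parameters is stable at this
    scale while the run stays desk-sized.
    """
    box = default_box(sommer_wall)
    pwv = make_pwv_model(
        sommer_wall, fluid, kind="simulation",
        simulation_kwargs={"n_cycles": 4, "quad_n": 11, "n_elements": 10},
    )
    return sobol_indices(pwv, box, n=8, seed=5)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
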