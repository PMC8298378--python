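"""YAML configuration: reading, defaults and assembly into run objects.

The configuration is a flat, human-readable file with sections
``wall / fluid / mesh / bcs / run / sensitivity``; file units are kPa,
degrees and mmHg, converted to CGS on load. The packaged default
(``data/reference_cca.yaml``) is the reference common carotid with
synthetic boundary conditions.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import yaml

from .boundaries import InflowWaveform, WindkesselParams, synth_inflow
from .solver import SimulationConfig, VesselMesh
from .tube_laws import TubeLaw
from .units import MMHG
from .wall import FluidProperties, HyperelasticTubeLaw, WallParameters

__all__ = [
    "default_config",
    "load_config",
    "wall_from_config",
    "fluid_from_config",
    "bcs_from_config",
    "build_simulation",
]


def default_config() -> dict:
    """The packaged reference-carotid configuration."""
    text = (
        resources.files("elastotube.data")
        .joinpath("reference_cca.yaml")
        .read_text()
    )
    return yaml.safe_load(text)


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, val in (override or {}).items():
        if isinstance(val, dict) and isinstance(base.get(key), dict):
            out[key] = _merge(base[key], val)
        else:
            out[key] = val
    return out


def load_config(path: str | Path | None = None) -> dict:
    """Load a config file on top of the packaged defaults (missing keys
    fall back to the reference carotid)."""
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            cfg = _merge(cfg, yaml.safe_load(fh) or {})
    return cfg


def wall_from_config(cfg: dict) -> WallParameters:
    w = cfg["wall"]
    return WallParameters.from_io_units(
        H=float(w["H"]),
        R_i=float(w["R_i"]),
        omega_deg=float(w["omega_deg"]),
        k0_kpa=float(w["k0_kpa"]),
        k1_kpa=float(w["k1_kpa"]),
        k2=float(w["k2"]),
        alpha=float(w["alpha"]),
        phi_deg=w["phi_deg"],
        lambda_z=float(w["lambda_z"]),
        L=float(w.get("L", 9.0)),
    )


def fluid_from_config(cfg: dict) -> FluidProperties:
    f = cfg.get("fluid", {})
    return FluidProperties(rho=float(f.get("rho", 1.06)),
                           mu=float(f.get("mu", 0.04)))


def bcs_from_config(cfg: dict):
    bcs = cfg["bcs"]
    inflow_cfg = bcs["inflow"]
    if "csv" in inflow_cfg:
        inflow = InflowWaveform.from_csv(
            inflow_cfg["csv"], period=inflow_cfg.get("period")
        )
    else:
        inflow = synth_inflow(
            mean_q=float(inflow_cfg["mean_q"]),
            peak_q=float(inflow_cfg["peak_q"]),
            period=float(inflow_cfg["period"]),
            systolic_fraction=float(inflow_cfg.get("systolic_fraction", 0.3)),
        )
    wk = bcs["windkessel"]
    windkessel = WindkesselParams(
        R1=float(wk["R1"]), C=float(wk["C"]), R2=float(wk["R2"]),
        P_out=float(wk.get("P_out", 0.0)),
    )
    return inflow, windkessel


def build_simulation(
    cfg: dict,
    tube_law: TubeLaw | None = None,
    n_cycles: int | None = None,
) -> SimulationConfig:
    """Assemble a ready-to-run :class:`SimulationConfig` from a config
    dict (hyperelastic law by default; pass ``tube_law`` for a calibrated
    linear surrogate)."""
    wall = wall_from_config(cfg)
    fluid = fluid_from_config(cfg)
    inflow, windkessel = bcs_from_config(cfg)
    run = cfg.get("run", {})
    mesh_cfg = cfg.get("mesh", {})
    length = (wall.L if mesh_cfg.get("use_stress_free_length", False)
              else wall.loaded_length)
    mesh = VesselMesh(length=length,
                      n_elements=int(mesh_cfg.get("n_elements", 14)))
    law = tube_law or HyperelasticTubeLaw(
        wall, quad_n=int(run.get("quad_n", 21))
    )
    return SimulationConfig(
        tube_law=law,
        mesh=mesh,
        fluid=fluid,
        inflow=inflow,
        windkessel=windkessel,
        n_cycles=int(n_cycles or run.get("n_cycles", 10)),
        cfl=float(run.get("cfl", 2.5)),
        p_init=float(run.get("p_init_mmhg", 80.0)) * MMHG,
    )
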