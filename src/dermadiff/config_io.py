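"""Configuration files, result writers and run manifests.

Scenario configurations round-trip through a flat, diff-friendly YAML
dialect. All on-disk values are SI with the unit recorded per field; result
CSVs carry the reporting unit in each column header.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import asdict
from pathlib import Path
from typing import Optional, Union

import pandas as pd
import yaml

from . import __version__
from .domain_model import (
    FENTANYL,
    DrugSpec,
    LayerStack,
    MaterialProps,
    MeshControls,
    ReservoirSpec,
    ScenarioConfig,
)
from .metrics import mass_ledger, release_summary
from .solver_1d import SimulationResult
from .units import FLOW_SI_TO_UG_PER_H, FLUX_SI_TO_UG_PER_CM2_H, KG_TO_MG

__all__ = [
    "scenario_to_dict",
    "scenario_from_dict",
    "save_config",
    "load_config",
    "result_frame",
    "write_result",
    "RunManifest",
]

_UNITS = {
    "thickness": "m",
    "D_z": "m^2 s^-1",
    "D_xy": "m^2 s^-1",
    "K": "1",
    "width": "m",
    "initial_concentration": "kg m^-3",
    "lateral_margin": "m",
    "removal_time_h": "h",
    "horizon_h": "h",
    "max_time_step_s": "s",
}


def scenario_to_dict(config: ScenarioConfig) -> dict:
    return {
        "name": config.name,
        "drug": asdict(config.drug),
        "layers": [asdict(m) for m in config.stack.layers],
        "reservoir": asdict(config.reservoir),
        "dimensionality": config.dimensionality,
        "lateral_margin": config.lateral_margin,
        "removal_time_h": config.removal_time_h,
        "horizon_h": config.horizon_h,
        "max_time_step_s": config.max_time_step_s,
        "mesh": asdict(config.mesh),
        "units": _UNITS,
    }


def scenario_from_dict(data: dict) -> ScenarioConfig:
    try:
        layers = tuple(MaterialProps(**m) for m in data["layers"])
        return ScenarioConfig(
            stack=LayerStack(layers),
            reservoir=ReservoirSpec(**data["reservoir"]),
            drug=DrugSpec(**data["drug"]) if "drug" in data else FENTANYL,
            dimensionality=data.get("dimensionality", "1D"),
            lateral_margin=data.get("lateral_margin"),
            removal_time_h=data.get("removal_time_h"),
            horizon_h=data.get("horizon_h", 240.0),
            max_time_step_s=data.get("max_time_step_s", 600.0),
            mesh=MeshControls(**data.get("mesh", {})),
            name=data.get("name", "custom"),
        )
    except (TypeError, KeyError, ValueError) as exc:
        raise ValueError(f"invalid scenario configuration: {exc}") from exc


def save_config(config: ScenarioConfig, path: Union[str, Path]) -> None:
    Path(path).write_text(yaml.safe_dump(scenario_to_dict(config), sort_keys=False))


def load_config(path: Union[str, Path]) -> ScenarioConfig:
    return scenario_from_dict(yaml.safe_load(Path(path).read_text()))


def result_frame(result: SimulationResult) -> pd.DataFrame:
    """Tidy per-time table with documented column units."""
    df = pd.DataFrame(
        {
            "time [h]": result.t_h,
            "m_pt_res [mg]": result.m_pt_res * KG_TO_MG,
            "m_ep_stor [mg]": result.m_ep_stor * KG_TO_MG,
            "m_pt_rel [mg]": result.m_pt_rel * KG_TO_MG,
            "m_bl_up [mg]": result.m_bl_up * KG_TO_MG,
            "g_pt_rel [ug cm^-2 h^-1]": result.g_pt_rel * FLUX_SI_TO_UG_PER_CM2_H,
            "g_bl_up [ug cm^-2 h^-1]": result.g_bl_up * FLUX_SI_TO_UG_PER_CM2_H,
            "G_pt_rel [ug h^-1]": result.G_pt_rel * FLOW_SI_TO_UG_PER_H,
            "G_bl_up [ug h^-1]": result.G_bl_up * FLOW_SI_TO_UG_PER_H,
        }
    )
    try:
        df["c_sc_max [kg m^-3]"] = result.c_sc_max
    except ValueError:
        pass
    return df


def snapshot_frame(result: SimulationResult, time_h: float) -> pd.DataFrame:
    """Vertical field snapshot (z, layer, psi, c) nearest to ``time_h``."""
    fld = result.field_at(time_h)
    mesh = result.mesh
    return pd.DataFrame(
        {
            "z [m]": mesh.centers,
            "layer": [mesh.labels[i] for i in mesh.layer_index],
            "psi [kg m^-3]": fld.psi,
            "c [kg m^-3]": fld.concentration,
        }
    )


class RunManifest:
    """Provenance record: the resolved configuration plus solver settings
    and bookkeeping that fully determine a run."""

    def __init__(self, config: ScenarioConfig):
        self.config = config
        self.started = _dt.datetime.now().isoformat(timespec="seconds")
        self.finished: Optional[str] = None
        self.mass_balance_residual: Optional[float] = None
        self.outputs: list = []

    def complete(self, result: Optional[SimulationResult] = None) -> None:
        self.finished = _dt.datetime.now().isoformat(timespec="seconds")
        if result is not None and result.config.reservoir.regime == "finite":
            self.mass_balance_residual = float(
                mass_ledger(result)["balance_residual"].max()
            )

    def to_dict(self) -> dict:
        return {
            "software": {"name": "dermadiff", "version": __version__},
            "config": scenario_to_dict(self.config),
            "started": self.started,
            "finished": self.finished,
            "mass_balance_residual": self.mass_balance_residual,
            "outputs": self.outputs,
        }


def write_result(
    result: SimulationResult, outdir: Union[str, Path], stem: Optional[str] = None
) -> dict:
    """Write the per-time CSV, a JSON summary and the run manifest.

    Returns the summary dict. Infinite-regime runs get a reduced summary
    (no mass ledger)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stem = stem or result.config.name
    manifest = RunManifest(result.config)
    csv_path = outdir / f"{stem}.csv"
    result_frame(result).to_csv(csv_path, index=False)
    manifest.outputs.append(csv_path.name)
    if result.config.reservoir.regime == "finite":
        summary = release_summary(result).to_dict()
    else:
        G = result.G_bl_up * FLOW_SI_TO_UG_PER_H
        summary = {
            "steady_g_bl_up_ug_cm2_h": float(
                result.g_bl_up[-1] * FLUX_SI_TO_UG_PER_CM2_H
            ),
            "G_bl_up_72h_ug_h": result.at_time(72.0, G),
            "m_bl_up_72h_mg": result.at_time(72.0, result.m_bl_up) * KG_TO_MG,
        }
    json_path = outdir / f"{stem}_summary.json"
    json_path.write_text(json.dumps(summary, indent=2))
    manifest.outputs.append(json_path.name)
    manifest.complete(result)
    (outdir / f"{stem}_manifest.json").write_text(
        json.dumps(manifest.to_dict(), indent=2)
    )
    return summary
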