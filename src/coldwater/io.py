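"""Configuration loading, validation, and output serialization.

Scenario/body/control bundles are described in YAML (or JSON) documents,
validated through pydantic models with explicit units in every error
message, and round-trip losslessly.  Run outputs are a long-format CSV
time series, a JSON summary, and a JSON run manifest (version, scenario
hash, solver options, seed, timestamps, file list).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from . import __version__
from .body import BodyModel, build_default_body
from .control import ControlParams
from .scenarios import (
    Scenario,
    T_FLOOR,
    builtin_rewarming_scenarios,
    builtin_scenarios,
)
from .solver import SimulationResult

__all__ = [
    "RunManifest",
    "ConfigBundle",
    "load_config",
    "save_config",
    "write_outputs",
    "config_json_schema",
]


class _ScenarioDoc(BaseModel):
    model_config = ConfigDict(extra="forbid")

    label: str
    medium: str
    T_ext: float = Field(description="environment temperature, °C")
    h: float | None = Field(None, ge=0, description="heat transfer coefficient, W/(m²·°C)")
    mode: str = "cooling"
    t_max_min: float = Field(240.0, gt=0, description="maximum simulated time, min")
    record_every_s: float = Field(15.0, gt=0, description="recording interval, s")

    @model_validator(mode="after")
    def _check_floor(self):
        floor = T_FLOOR.get(self.medium)
        if floor is None:
            raise ValueError(f"medium must be one of {sorted(T_FLOOR)}")
        if self.T_ext < floor:
            raise ValueError(
                f"T_ext={self.T_ext} °C below the {self.medium} floor of {floor} °C"
            )
        return self

    def to_scenario(self) -> Scenario:
        return Scenario(**self.model_dump())


class _ThermoregulationDoc(BaseModel):
    model_config = ConfigDict(extra="forbid")

    tc_set: float = 37.0
    ts_set: float = 34.5
    g_core_W: float = Field(70.0, ge=0)
    g_skin_W: float = Field(10.0, ge=0)
    q_shiv_max_W: float = Field(350.0, ge=0)
    shiver_scale: float = Field(ControlParams().shiver_scale, ge=0)
    a_s: float = Field(0.2, ge=0)
    f_min: float = Field(0.1, gt=0, le=1)
    f_min_muscle: float = Field(0.7, gt=0, le=1)
    a_d: float = Field(1.5, ge=0)
    f_max: float = Field(12.0, ge=1)
    enabled: bool = True

    def to_params(self) -> ControlParams:
        return ControlParams(**self.model_dump())


class _SolverDoc(BaseModel):
    model_config = ConfigDict(extra="forbid")

    nr: int = Field(160, ge=8, description="radial nodes per segment")
    dt: float = Field(1.0, gt=0, description="time step, s")
    theta: float = Field(0.5, ge=0, le=1)
    basal_offset: bool = True


@dataclass
class ConfigBundle:
    """Validated run configuration: scenarios + body + controls + solver."""

    scenarios: list[Scenario]
    body: BodyModel
    controls: ControlParams
    solver_options: dict

    def to_dict(self) -> dict:
        ctrl = self.controls
        return {
            "scenarios": [s.to_dict() for s in self.scenarios],
            "body": self.body.to_dict(),
            "thermoregulation": {
                "tc_set": ctrl.tc_set, "ts_set": ctrl.ts_set,
                "g_core_W": ctrl.g_core_W, "g_skin_W": ctrl.g_skin_W,
                "q_shiv_max_W": ctrl.q_shiv_max_W, "shiver_scale": ctrl.shiver_scale,
                "a_s": ctrl.a_s, "f_min": ctrl.f_min,
                "f_min_muscle": ctrl.f_min_muscle, "enabled": ctrl.enabled,
            },
            "solver": dict(self.solver_options),
        }


def _resolve_named_scenarios(names: list[str]) -> list[Scenario]:
    catalog = {s.label: s for s in builtin_scenarios() + builtin_rewarming_scenarios()}
    out = []
    for name in names:
        if name not in catalog:
            raise ValueError(
                f"unknown built-in scenario {name!r}; available: {sorted(catalog)}"
            )
        out.append(catalog[name])
    return out


def load_config(path: str | Path) -> ConfigBundle:
    """Load and validate a YAML/JSON run configuration.

    A minimal document may name built-in scenarios only
    (``scenarios: [fresh_still_5C]``); body, thermoregulation and solver
    blocks default to the bundled average body, the calibrated control
    set, and the standard solver options.
    """
    path = Path(path)
    text = path.read_text()
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: config must be a mapping")

    raw_scenarios = doc.get("scenarios", [])
    if "scenario" in doc:
        raw_scenarios = [doc["scenario"]] + list(raw_scenarios)
    scenarios: list[Scenario] = []
    names: list[str] = []
    for item in raw_scenarios:
        if isinstance(item, str):
            names.append(item)
        else:
            try:
                scenarios.append(_ScenarioDoc(**item).to_scenario())
            except ValidationError as exc:
                raise ValueError(f"{path}: invalid scenario block: {exc}") from exc
    scenarios = _resolve_named_scenarios(names) + scenarios
    if not scenarios:
        raise ValueError(f"{path}: no scenarios defined")

    body = (
        BodyModel.from_dict(doc["body"]) if "body" in doc else build_default_body()
    )
    try:
        controls = _ThermoregulationDoc(**doc.get("thermoregulation", {})).to_params()
        solver = _SolverDoc(**doc.get("solver", {})).model_dump()
    except ValidationError as exc:
        raise ValueError(f"{path}: invalid configuration: {exc}") from exc
    return ConfigBundle(scenarios=scenarios, body=body, controls=controls, solver_options=solver)


def config_json_schema() -> dict:
    """JSON schema of the scenario/thermoregulation/solver config blocks.

    Derived from the validation models themselves, so it cannot drift from
    what ``load_config`` accepts.
    """
    return {
        "$schema": "https://json-schema.org/draft/2020-12/schema",
        "title": "coldwater run configuration",
        "type": "object",
        "properties": {
            "scenarios": {
                "type": "array",
                "items": {
                    "anyOf": [
                        {"type": "string", "description": "built-in scenario label"},
                        _ScenarioDoc.model_json_schema(),
                    ]
                },
            },
            "body": {"type": "object", "description": "BodyModel.to_dict document"},
            "thermoregulation": _ThermoregulationDoc.model_json_schema(),
            "solver": _SolverDoc.model_json_schema(),
        },
        "required": ["scenarios"],
    }


def save_config(bundle: ConfigBundle, path: str | Path) -> None:
    """Write a bundle back to YAML; ``load_config`` round-trips it."""
    Path(path).write_text(yaml.safe_dump(bundle.to_dict(), sort_keys=False))


@dataclass
class RunManifest:
    """Provenance record written next to every output set."""

    scenario_hash: str
    solver_options: dict
    seed: int | None = None
    version: str = __version__
    created_utc: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )
    outputs: list[str] = field(default_factory=list)

    @classmethod
    def for_run(cls, scenario: Scenario, solver_options: dict, seed: int | None = None):
        blob = json.dumps(scenario.to_dict(), sort_keys=True).encode()
        return cls(
            scenario_hash=hashlib.sha256(blob).hexdigest()[:16],
            solver_options=dict(solver_options),
            seed=seed,
        )

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "scenario_hash": self.scenario_hash,
            "solver_options": self.solver_options,
            "seed": self.seed,
            "created_utc": self.created_utc,
            "outputs": list(self.outputs),
        }


def write_outputs(
    result: SimulationResult,
    summary: dict,
    manifest: RunManifest,
    outdir: str | Path,
    *,
    stem: str = "run",
) -> dict[str, Path]:
    """Write the CSV time series, JSON summary and manifest.

    Returns the mapping of artifact kind → path.  Column order of the CSV
    is fixed (time_s, variable, segment, value); temperatures are °C,
    shivering power W, time s.
    """
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "timeseries": outdir / f"{stem}_timeseries.csv",
            "summary": outdir / f"{stem}_summary.json",
            "manifest": outdir / f"{stem}_manifest.json",
        }
        result.to_frame().to_csv(paths["timeseries"], index=False)
        paths["summary"].write_text(json.dumps(summary, indent=2, allow_nan=True))
        manifest.outputs = [p.name for k, p in paths.items() if k != "manifest"]
        paths["manifest"].write_text(json.dumps(manifest.to_dict(), indent=2))
    except OSError as exc:
        raise OSError(f"failed writing outputs under {outdir}: {exc}") from exc
    return paths
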