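"""Loading of structured simulation configurations.

A scenario file is a YAML document mirroring the experimental
configuration keys: species/tracer metadata, the diffusion
coefficient, per-scala perfusion routes, scala-scala and scala-blood
communication half-times and the numerical grid.  The three tracer
scenarios (both perilymphatic scalae perfused, or only one of them)
ship as package data.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass
from typing import Mapping

import yaml

from .errors import ValidationError
from .fluids import (CommunicationSpec, PerfusionRoute, PerfusionSpec,
                     ProbeSpec, ScalaGeometry, SimulationConfig,
                     default_geometries)

__all__ = [
    "ScenarioSpec",
    "TRACER_SCENARIOS",
    "OSMOTIC_SCENARIOS",
    "load_scenario",
    "load_osmotic_defaults",
]

#: Tracer scenario name -> packaged YAML file.
TRACER_SCENARIOS = {
    "SV+ST/SM": "sv_st_sm.yaml",
    "SV/SM": "sv_sm.yaml",
    "ST/SM": "st_sm.yaml",
}

OSMOTIC_SCENARIOS = ("osmotic-CDE", "osmotic-OSC")

#: Communication tuned against the 7-min in vivo probe value, per scenario.
CALIBRATED_COMM = {"SV+ST/SM": "sv_sm", "SV/SM": "sv_sm", "ST/SM": "st_sm"}


@dataclass(frozen=True)
class ScenarioSpec:
    name: str
    species: str
    tracer: str
    geometries: Mapping[str, ScalaGeometry]
    comms: CommunicationSpec
    perfusion: PerfusionSpec
    config: SimulationConfig
    raw: dict

    def snapshot(self) -> dict:
        """Full parameter snapshot for reproducible re-runs."""
        return json.loads(json.dumps(self.raw))


def _geometries_from(doc: dict) -> dict[str, ScalaGeometry]:
    geo = doc.get("geometry", "default")
    if geo == "default":
        return default_geometries()
    out = {}
    for name, g in geo.items():
        out[name] = ScalaGeometry(
            scala=name, length_mm=float(g["length_mm"]),
            profile_x_mm=tuple(float(x) for x in g["profile_x_mm"]),
            profile_area_mm2=tuple(float(a) for a in g["profile_area_mm2"]))
    return out


def _spec_from_doc(name: str, doc: dict) -> ScenarioSpec:
    try:
        comms = CommunicationSpec(**{k: (None if v is None else float(v))
                                     for k, v in doc["communications"].items()})
        routes = {}
        for scala, r in doc.get("perfusion", {}).get("scalae", {}).items():
            routes[scala] = PerfusionRoute(
                rate_ul_min=float(r["rate_ul_min"]),
                inlet_conc_pct=float(r["inlet_conc_pct"]),
                entry_mm=float(r["entry_mm"]),
                exit_mm=float(r["exit_mm"]),
                start_min=float(r.get("start_min", 0.0)),
                stop_min=None if r.get("stop_min") is None else float(r["stop_min"]))
        sim = doc["sim"]
        config = SimulationConfig(
            diffusion_coeff_cm2_s=float(doc["diffusion_coeff_cm2_s"]),
            dx_mm=float(sim["dx_mm"]),
            dt_s=float(sim["dt_s"]),
            duration_min=float(sim["duration_min"]),
            output_dt_min=float(sim.get("output_dt_min", 0.25)),
            probes=tuple(ProbeSpec(p["scala"], float(p["x_mm"]))
                         for p in sim["probes"]))
    except KeyError as exc:
        raise ValidationError(f"scenario {name!r}: missing key {exc}") from exc
    return ScenarioSpec(name=name, species=str(doc.get("species", "")),
                        tracer=str(doc.get("tracer", "")),
                        geometries=_geometries_from(doc), comms=comms,
                        perfusion=PerfusionSpec(routes=routes), config=config,
                        raw=doc)


def load_scenario(name_or_path: str) -> ScenarioSpec:
    """Load a packaged tracer scenario by name, or any YAML file by path."""
    if name_or_path in TRACER_SCENARIOS:
        ref = (importlib.resources.files("cochperm.data")
               / "scenarios" / TRACER_SCENARIOS[name_or_path])
        with importlib.resources.as_file(ref) as path:
            with open(path) as fh:
                doc = yaml.safe_load(fh)
        return _spec_from_doc(name_or_path, doc)
    try:
        with open(name_or_path) as fh:
            doc = yaml.safe_load(fh)
    except OSError as exc:
        raise ValidationError(
            f"unknown scenario {name_or_path!r}: not a packaged name "
            f"({sorted(TRACER_SCENARIOS)}) and not a readable file") from exc
    return _spec_from_doc(str(name_or_path), doc)


def load_osmotic_defaults() -> dict:
    """Packaged default parameter sheet for the osmotic scenarios."""
    ref = importlib.resources.files("cochperm.data") / "osmotic_defaults.json"
    with importlib.resources.as_file(ref) as path:
        with open(path) as fh:
            return json.load(fh)
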