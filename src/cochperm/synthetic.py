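"""Seeded generators for every input class the pipeline consumes.

Morphometry tables, replicate length measurements, and in-vivo-style
observation records (7-min tracer probe readings and osmotic
solute-increase percentages) can all be produced synthetically so the
full analysis chain is testable offline.  Lengths get multiplicative
log-normal noise truncated at +/-3 sigma (they cannot go negative);
concentrations get additive normal noise clipped to [0, 100].  Ground
truth is always serialised next to the noisy record so recovery tests
never have to re-derive it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .errors import ValidationError
from .fluids import SimulationConfig, probe, simulate_dispersal
from .morphometry import SEGMENT_LABELS, HalfTurnTable, compute_partition_areas
from .scenarios import TRACER_SCENARIOS, load_osmotic_defaults, load_scenario

__all__ = [
    "SynthConfig",
    "BASE_LENGTHS_UM",
    "BASE_RM_WIDTHS_UM",
    "BASE_OC_WIDTHS_UM",
    "gen_morphometry",
    "gen_replicates",
    "gen_observations",
]

#: Smooth base-to-apex trend used as the noiseless morphometry profile.
BASE_LENGTHS_UM = (800.0, 3800.0, 3200.0, 2700.0, 2300.0, 1900.0, 1600.0, 1300.0, 900.0)
BASE_RM_WIDTHS_UM = (420.0, 450.0, 480.0, 520.0, 560.0, 600.0, 640.0, 680.0)
BASE_OC_WIDTHS_UM = (180.0, 200.0, 230.0, 260.0, 300.0, 340.0, 380.0, 420.0)

_SCENARIOS = tuple(TRACER_SCENARIOS) + ("osmotic",)


@dataclass(frozen=True)
class SynthConfig:
    """Configuration for all generators; the seed is mandatory."""

    seed: int
    scenario: str = "SV+ST/SM"
    n_specimens: int = 3
    replicate_cv_pct: float = 3.0
    morphometry_cv_pct: float = 0.0
    observation_cv_pct: float = 3.0

    def __post_init__(self):
        for name in ("replicate_cv_pct", "morphometry_cv_pct", "observation_cv_pct"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.n_specimens < 1:
            raise ValidationError("n_specimens must be >= 1")


def _truncated_lognormal_factors(rng: np.random.Generator, n: int,
                                 cv_pct: float) -> np.ndarray:
    """Multiplicative noise factors, log-normal truncated at +/-3 sigma."""
    if cv_pct == 0:
        return np.ones(n)
    sigma = math.sqrt(math.log(1.0 + (cv_pct / 100.0) ** 2))
    z = rng.standard_normal(n)
    z = np.clip(z, -3.0, 3.0)
    return np.exp(sigma * z - 0.5 * sigma ** 2)


def gen_morphometry(cfg: SynthConfig,
                    target_totals_mm2: tuple[float, float] | None = None,
                    ) -> HalfTurnTable:
    """Synthetic half-turn table with optional exact area calibration.

    ``target_totals_mm2 = (rm_total, oc_total)`` rescales the noisy
    widths per partition so the trapezoidal totals hit the targets
    exactly (the total is linear in a uniform width scaling).
    """
    rng = np.random.default_rng(cfg.seed)
    w_rm = np.array(BASE_RM_WIDTHS_UM) * _truncated_lognormal_factors(
        rng, 8, cfg.morphometry_cv_pct)
    w_oc = np.array(BASE_OC_WIDTHS_UM) * _truncated_lognormal_factors(
        rng, 8, cfg.morphometry_cv_pct)
    table = HalfTurnTable(labels=SEGMENT_LABELS, w_rm_um=tuple(w_rm),
                          w_oc_um=tuple(w_oc), l_um=BASE_LENGTHS_UM)
    if target_totals_mm2 is not None:
        rm_target, oc_target = target_totals_mm2
        rm_now = compute_partition_areas(table, "RM").total_mm2
        oc_now = compute_partition_areas(table, "OC").total_mm2
        table = HalfTurnTable(
            labels=SEGMENT_LABELS,
            w_rm_um=tuple(w_rm * (rm_target / rm_now)),
            w_oc_um=tuple(w_oc * (oc_target / oc_now)),
            l_um=BASE_LENGTHS_UM)
    return table


def gen_replicates(mean: float, sd: float, n: int, seed: int) -> np.ndarray:
    """``n`` normal draws around ``mean`` with spread ``sd`` (deterministic per seed)."""
    if sd < 0:
        raise ValidationError("sd must be >= 0")
    if n < 1:
        raise ValidationError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return mean + sd * rng.standard_normal(n)


def gen_observations(scenario: str, cfg: SynthConfig,
                     ground_truth_half_times: Mapping[str, float] | None = None,
                     si_truth_pct: tuple[float, float] | None = None,
                     sim_config: SimulationConfig | None = None) -> dict:
    """In-vivo-style observation record with serialised ground truth.

    Tracer scenarios run the forward simulator with the scenario's (or
    the supplied) half-times and report the 7-min endolymph probe value
    plus noise.  The osmotic scenario reports the two solute-increase
    percentages around configurable truth values.
    """
    if scenario not in _SCENARIOS:
        raise ValidationError(
            f"unknown scenario {scenario!r}; expected one of {_SCENARIOS}")
    rng = np.random.default_rng(cfg.seed)
    if scenario == "osmotic":
        defaults = load_osmotic_defaults()
        if si_truth_pct is None:
            si_truth_pct = (defaults["si_area_pct"], defaults["si_movement_pct"])
        si_area, si_movement = si_truth_pct
        noise = rng.standard_normal(2) * (cfg.observation_cv_pct / 100.0)
        return {
            "scenario": scenario,
            "kind": "osmotic",
            "observed": {
                "si_area_pct": float(si_area * (1.0 + noise[0])),
                "si_movement_pct": float(si_movement * (1.0 + noise[1])),
            },
            "ground_truth": {"si_area_pct": si_area, "si_movement_pct": si_movement},
            "seed": cfg.seed,
        }
    spec = load_scenario(scenario)
    comms = spec.comms
    if ground_truth_half_times:
        comms = replace(comms, **{f"{k}_min": v
                                  for k, v in ground_truth_half_times.items()})
    config = sim_config if sim_config is not None else spec.config
    config = replace(config, duration_min=8.0, output_dt_min=min(config.output_dt_min, 0.25))
    result = simulate_dispersal(spec.geometries, comms, spec.perfusion, config)
    probe_id = config.probes[0].probe_id
    truth = probe(result.timecourses[probe_id], 7.0)
    noisy = truth + rng.standard_normal() * (cfg.observation_cv_pct / 100.0) * truth
    noisy = float(np.clip(noisy, 0.0, 100.0))
    return {
        "scenario": scenario,
        "kind": "tracer",
        "probe": probe_id,
        "time_min": 7.0,
        "observed": {"concentration_pct": noisy},
        "ground_truth": {
            "concentration_pct": truth,
            "half_times_min": {
                "sv_sm": comms.sv_sm_min,
                "st_sv": comms.st_sv_min,
                "st_sm": comms.st_sm_min,
            },
        },
        "seed": cfg.seed,
    }
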