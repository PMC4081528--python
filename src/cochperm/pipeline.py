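"""Stage orchestration: areas -> simulation -> fit -> permeability.

Five named scenarios are supported.  The three tracer scenarios chain
surface-area morphometry, the dispersal simulation (optionally
re-calibrated against a 7-min observation), the uptake-model fit and
the diffusional-permeability formula.  The two osmotic scenarios are
closed-form: volume flow from the solute increase, then the osmotic
coefficient, the P_f/P_D ratio and (for the outer-sulcus-cell shunt)
the channel-density estimate.
"""

from __future__ import annotations

import csv
import json
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import kinetics, morphometry, permeability
from .errors import CochpermError, ValidationError
from .fluids import DispersalResult, probe, simulate_dispersal, calibrate_half_time
from .scenarios import (CALIBRATED_COMM, OSMOTIC_SCENARIOS, TRACER_SCENARIOS,
                        ScenarioSpec, load_osmotic_defaults, load_scenario)

__all__ = ["PipelineRun", "run_pipeline", "render_report"]

ALL_SCENARIOS = tuple(TRACER_SCENARIOS) + OSMOTIC_SCENARIOS


def json_default(obj):
    """Serializer hook for numpy scalars/arrays in report metadata."""
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj).__name__}")


@dataclass
class PipelineRun:
    """Outputs and the resolved configuration snapshot of one run."""

    run_id: str
    scenario: str
    config_snapshot: dict
    summary_rows: list[dict] = field(default_factory=list)
    outputs: dict = field(default_factory=dict)
    log: list[str] = field(default_factory=list)

    def add_row(self, quantity: str, value: float, units: str, **inputs):
        self.summary_rows.append({
            "scenario": self.scenario, "quantity": quantity,
            "value": value, "units": units,
            "inputs": json.dumps(inputs, sort_keys=True)})


def _stage(run: PipelineRun, name: str):
    run.log.append(f"stage:{name}")
    return name


def run_pipeline(scenario: str,
                 table: morphometry.HalfTurnTable | None = None,
                 observation: dict | None = None,
                 scenario_spec: ScenarioSpec | None = None,
                 overrides: dict | None = None,
                 run_id: str | None = None) -> PipelineRun:
    """Execute the stage chain for one scenario.

    ``observation`` is an in-vivo-style record (see
    :mod:`cochperm.synthetic`); for tracer scenarios its 7-min probe
    value drives a half-time calibration before the production run.
    ``overrides`` replaces entries of the osmotic parameter sheet.
    Any stage failure is re-raised annotated with the stage name.
    """
    if scenario not in ALL_SCENARIOS:
        raise ValidationError(
            f"unknown scenario {scenario!r}; expected one of {ALL_SCENARIOS}")
    if table is None:
        table = morphometry.default_half_turn_table()
    defaults = load_osmotic_defaults()
    if overrides:
        defaults = {**defaults, **overrides}
    run = PipelineRun(
        run_id=run_id or f"{scenario.replace('/', '-')}-{int(time.time())}",
        scenario=scenario,
        config_snapshot={"scenario": scenario, "osmotic_defaults": defaults})
    stage = "init"
    try:
        stage = _stage(run, "areas")
        rm = morphometry.compute_partition_areas(table, "RM")
        oc = morphometry.compute_partition_areas(table, "OC")
        run.outputs["areas"] = morphometry.areas_report(table)
        run.add_row("A_SV/SM", rm.total_mm2, "mm^2")
        run.add_row("A_ST/SM", oc.total_mm2, "mm^2")
        run.add_row("A_SV+ST/SM", rm.total_mm2 + oc.total_mm2, "mm^2")
        if scenario in TRACER_SCENARIOS:
            _run_tracer(run, scenario, rm, oc, defaults, observation,
                        scenario_spec)
        elif scenario == "osmotic-CDE":
            _run_osmotic_cde(run, rm, oc, defaults, observation)
        else:
            _run_osmotic_osc(run, defaults, observation)
    except CochpermError as exc:
        failed = run.log[-1].split(":", 1)[1] if run.log else stage
        raise type(exc)(f"[stage {failed}] {exc}") from exc
    return run


def _scenario_area(scenario, rm, oc):
    if scenario == "SV/SM":
        return rm.total_mm2
    if scenario == "ST/SM":
        return oc.total_mm2
    return rm.total_mm2 + oc.total_mm2


def _run_tracer(run, scenario, rm, oc, defaults, observation, scenario_spec):
    spec = scenario_spec if scenario_spec is not None else load_scenario(scenario)
    run.config_snapshot["simulation"] = spec.snapshot()
    comms = spec.comms
    if observation is not None:
        stage = _stage(run, "calibrate")
        which = CALIBRATED_COMM[scenario]
        target = (observation["probe"], float(observation["time_min"]),
                  float(observation["observed"]["concentration_pct"]))
        cal = calibrate_half_time(spec.geometries, comms, spec.perfusion,
                                  spec.config, target=target, which=which)
        comms = replace(comms, **{f"{which}_min": cal.half_time_min})
        run.outputs["calibration"] = {
            "which": which, "half_time_min": cal.half_time_min,
            "achieved_conc_pct": cal.achieved_conc_pct,
            "target_conc_pct": cal.target_conc_pct,
            "converged": cal.converged, "unreachable": cal.unreachable}
        run.add_row(f"t_half({which})", cal.half_time_min, "min")
    _stage(run, "simulate")
    result = simulate_dispersal(spec.geometries, comms, spec.perfusion, spec.config)
    run.outputs["simulation"] = result
    run.outputs["mass_balance"] = result.balance.to_dict()
    _stage(run, "fit")
    sm_probe = spec.config.probes[0].probe_id
    tc = result.timecourses[sm_probe]
    t_grid = np.arange(0.0, spec.config.duration_min + 1e-9, 1.0)
    y_grid = np.array([probe(tc, t) for t in t_grid])
    fit = kinetics.fit_uptake_model(t_grid, y_grid)
    run.outputs["fit"] = fit.to_dict()
    p_prime, p_se = kinetics.extract_rate_constant(fit)
    run.add_row("P_prime", p_prime, "1/min", stderr=p_se)
    _stage(run, "permeability")
    area = _scenario_area(scenario, rm, oc)
    pd_res = permeability.compute_Pd(permeability.DiffusionalInputs(
        p_prime_per_min=p_prime, v_e_ul=defaults["v_e_ul"], area_mm2=area))
    run.outputs["P_D"] = pd_res
    run.add_row("P_D", pd_res.value_cm_s, "cm/s", **pd_res.inputs)


def _run_osmotic_cde(run, rm, oc, defaults, observation):
    _stage(run, "volume_flow")
    si = defaults["si_area_pct"]
    if observation is not None:
        si = float(observation["observed"]["si_area_pct"])
    area = rm.total_mm2 + oc.total_mm2
    jv = permeability.compute_Jv(defaults["v_e_ul"], si, defaults["duration_min"])
    run.add_row("J_v-Area", jv, "ul/min", si_pct=si)
    _stage(run, "permeability")
    pf = permeability.compute_Pf(permeability.OsmoticInputs(
        area_mm2=area, delta_c_mol_l=defaults["delta_c_mol_l"], jv_ul_min=jv))
    run.outputs["P_f"] = pf
    run.add_row("P_f", pf.value_cm_s, "cm/s", **pf.inputs)
    # reference P_D of the whole epithelium from its tabulated rate constant
    p_prime = defaults["rate_constants_per_min"]["SV+ST/SM"]["p_prime"]
    pd_res = permeability.compute_Pd(permeability.DiffusionalInputs(
        p_prime_per_min=p_prime, v_e_ul=defaults["v_e_ul"], area_mm2=area))
    run.outputs["P_D"] = pd_res
    run.add_row("P_D", pd_res.value_cm_s, "cm/s", **pd_res.inputs)
    ratio = permeability.compute_ratio(pf, pd_res)
    run.add_row("Pf/Pd", round(ratio, 2), "")


def _run_osmotic_osc(run, defaults, observation):
    _stage(run, "shunt_area")
    shunt = morphometry.compute_shunt_area(
        defaults["shunt_radial_width_um"],
        defaults["shunt_longitudinal_length_um"])
    run.outputs["shunt"] = shunt
    run.add_row("A_OSC", shunt.area_um2, "um^2")
    _stage(run, "volume_flow")
    si = defaults["si_movement_pct"]
    if observation is not None:
        si = float(observation["observed"]["si_movement_pct"])
    jv = permeability.compute_Jv(defaults["v_e_ul"], si, defaults["duration_min"])
    run.add_row("J_v-Movement", jv, "ul/min", si_pct=si)
    _stage(run, "permeability")
    pf = permeability.compute_Pf(permeability.OsmoticInputs(
        area_mm2=shunt.area_mm2, delta_c_mol_l=defaults["delta_c_mol_l"],
        jv_ul_min=jv))
    run.outputs["P_f"] = pf
    run.add_row("P_f", pf.value_cm_s, "cm/s", **pf.inputs)
    ref = permeability.load_reference_table()
    ref_vals = ref.loc[ref["aqp5_reference"] == 1, "P_D_1e-5_cm_s"].astype(float)
    mean_pd_1e5 = permeability.mean_reference_Pd(list(ref_vals))
    pd_res = permeability.PermeabilityResult(
        value_cm_s=mean_pd_1e5 * 1e-5, kind="P_D",
        inputs={"source": "mean of AQP5-expressing reference epithelia"})
    run.outputs["P_D"] = pd_res
    run.add_row("P_D(reference mean)", pd_res.value_cm_s, "cm/s")
    ratio = permeability.compute_ratio(pf, pd_res)
    run.add_row("Pf/Pd", round(ratio, 2), "")
    _stage(run, "channel_density")
    dens = permeability.estimate_channel_density(
        pf.value_cm_s, defaults["single_channel_pf_cm3_s"])
    run.outputs["channel_density"] = dens
    run.add_row("n_AQP5", dens.channels_per_um2, "1/um^2",
                note=dens.note)


def render_report(run: PipelineRun, outdir) -> dict[str, Path]:
    """Write the CSV summary, JSON artifacts and a text report.

    Returns the paths written.  A time-course plot with the fitted
    uptake-model overlay is produced when a simulation stage ran and
    matplotlib is importable.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    summary_path = outdir / "summary.csv"
    with open(summary_path, "w", newline="") as fh:
        writer = csv.DictWriter(
            fh, fieldnames=["scenario", "quantity", "value", "units", "inputs"])
        writer.writeheader()
        for row in run.summary_rows:
            writer.writerow(row)
    paths["summary_csv"] = summary_path

    meta = {"run_id": run.run_id, "scenario": run.scenario,
            "config": run.config_snapshot, "log": run.log}
    for key in ("areas", "fit", "mass_balance", "calibration"):
        if key in run.outputs:
            meta[key] = run.outputs[key]
    meta_path = outdir / "run.json"
    with open(meta_path, "w") as fh:
        json.dump(meta, fh, indent=2, default=json_default)
    paths["run_json"] = meta_path

    sim: DispersalResult | None = run.outputs.get("simulation")
    if sim is not None:
        tc_path = outdir / "timecourses.csv"
        with open(tc_path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["probe", "time_min", "concentration_pct"])
            for pid, tc in sim.timecourses.items():
                for t, c in zip(tc.times_min, tc.conc_pct):
                    writer.writerow([pid, f"{t:.6g}", f"{c:.10g}"])
        paths["timecourses_csv"] = tc_path
        plot_path = _maybe_plot(run, sim, outdir)
        if plot_path is not None:
            paths["plot"] = plot_path

    report_path = outdir / "report.txt"
    with open(report_path, "w") as fh:
        fh.write(f"run {run.run_id} -- scenario {run.scenario}\n")
        fh.write("-" * 60 + "\n")
        for row in run.summary_rows:
            fh.write(f"{row['quantity']:>24}: {row['value']:.6g} {row['units']}\n")
    paths["report_txt"] = report_path
    return paths


def _maybe_plot(run, sim, outdir) -> Path | None:
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError:
        return None
    fig, ax = plt.subplots(figsize=(6, 4))
    for pid, tc in sim.timecourses.items():
        ax.plot(tc.times_min, tc.conc_pct, label=pid)
    fit = run.outputs.get("fit")
    if fit:
        params = kinetics.KineticParams(fit["P_prime"], fit["P_doubleprime"],
                                        fit["alpha"], fit["C0"])
        t = np.linspace(0, float(sim.timecourses[next(iter(sim.timecourses))]
                                 .times_min[-1]), 400)
        ax.plot(t, kinetics.eval_uptake_model(params, t), "--",
                label="uptake-model fit")
    ax.set_xlabel("time (min)")
    ax.set_ylabel("concentration (% of perfusate)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    path = Path(outdir) / "timecourses.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
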