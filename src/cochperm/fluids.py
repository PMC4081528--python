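"""1-D tracer dispersal in the three coupled cochlear scalae.

Each scala (scala vestibuli SV, scala tympani ST, scala media SM) is a
1-D tube with a tabulated cross-sectional area profile.  Tracer moves
by molecular diffusion, by perfusion-driven advection between an entry
and an exit site, by first-order scala-scala exchange and by
first-order clearance to blood:

    dC/dt = (1/A) d/dx (A D dC/dx) - (Q/A) dC/dx
            + sum_j k_ij (C_j - C_i) - k_blood,i C_i

Exchange half-times parameterize the relaxation of the local
inter-scala concentration difference, k = ln2 / t_half; fluxes are
weighted by the reduced volume V_a V_b / (V_a + V_b) so the pairwise
update conserves tracer mass exactly and the concentration difference
of two well-mixed compartments decays as exp(-k t).

Numerics: operator splitting per time step -- one implicit tridiagonal
solve per scala combining Crank-Nicolson diffusion with backward-Euler
upwind advection in conservative flux form, then an exact exponential
update for each exchange pair and for blood clearance.  All fluxes are
accounted, so the mass balance closes to round-off.

Internal units: mm, minutes, microlitres (= mm^3), concentrations in
percent of perfusate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.linalg import solve_banded

from .errors import CalibrationError, ValidationError

__all__ = [
    "BLOCKED_HALF_TIME_MIN",
    "ScalaGeometry",
    "CommunicationSpec",
    "PerfusionRoute",
    "PerfusionSpec",
    "ProbeSpec",
    "SimulationConfig",
    "TimeCourse",
    "MassBalance",
    "DispersalResult",
    "CalibrationResult",
    "default_geometries",
    "simulate_dispersal",
    "probe",
    "mass_balance",
    "calibrate_half_time",
]

#: Sentinel half-time (min) denoting effectively blocked exchange.
BLOCKED_HALF_TIME_MIN = 9999.0

_CM2_S_TO_MM2_MIN = 100.0 * 60.0
LN2 = math.log(2.0)


@dataclass(frozen=True)
class ScalaGeometry:
    """Length and cross-sectional area profile of one scala.

    ``profile_x_mm``/``profile_area_mm2`` are breakpoints interpolated
    linearly onto the simulation grid.
    """

    scala: str
    length_mm: float
    profile_x_mm: tuple[float, ...]
    profile_area_mm2: tuple[float, ...]

    def __post_init__(self):
        if self.length_mm <= 0:
            raise ValidationError(f"{self.scala}: length must be positive")
        if len(self.profile_x_mm) != len(self.profile_area_mm2) or len(self.profile_x_mm) < 2:
            raise ValidationError(f"{self.scala}: need >= 2 area breakpoints")
        if any(a <= 0 for a in self.profile_area_mm2):
            raise ValidationError(f"{self.scala}: area profile must be positive everywhere")
        if list(self.profile_x_mm) != sorted(self.profile_x_mm):
            raise ValidationError(f"{self.scala}: profile x positions must be increasing")

    def area_at(self, x_mm: np.ndarray) -> np.ndarray:
        return np.interp(x_mm, self.profile_x_mm, self.profile_area_mm2)

    @property
    def volume_ul(self) -> float:
        """Total volume from the trapezoidal integral of the area profile."""
        x = np.linspace(0.0, self.length_mm, 2001)
        return float(np.trapezoid(self.area_at(x), x))

    @staticmethod
    def uniform(scala: str, length_mm: float, volume_ul: float) -> "ScalaGeometry":
        area = volume_ul / length_mm
        return ScalaGeometry(scala, length_mm, (0.0, length_mm), (area, area))


def default_geometries() -> dict[str, ScalaGeometry]:
    """Packaged guinea-pig-like geometry fixture.

    SV and ST taper from base to apex and end 15.5 mm and 16.2 mm from
    the base; SM has a uniform cross-section with its volume forced to
    the adult guinea-pig endolymph volume of 1.2 ul.
    """
    return {
        "SV": ScalaGeometry("SV", 15.5, (0.0, 15.5), (0.9, 0.25)),
        "ST": ScalaGeometry("ST", 16.2, (0.0, 16.2), (1.1, 0.25)),
        "SM": ScalaGeometry.uniform("SM", 14.0, 1.2),
    }


@dataclass(frozen=True)
class CommunicationSpec:
    """Pairwise scala-scala and scala-blood exchange half-times (min)."""

    sv_sm_min: float = 2.2
    st_sv_min: float = BLOCKED_HALF_TIME_MIN
    st_sm_min: float = 4.6
    sv_blood_min: float | None = 1.6
    st_blood_min: float | None = 1.6
    sm_blood_min: float | None = 15.0

    def __post_init__(self):
        for name in ("sv_sm_min", "st_sv_min", "st_sm_min",
                     "sv_blood_min", "st_blood_min", "sm_blood_min"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValidationError(f"half-time {name} must be positive, got {v}")

    def pair_half_times(self) -> dict[tuple[str, str], float]:
        return {("SV", "SM"): self.sv_sm_min,
                ("ST", "SV"): self.st_sv_min,
                ("ST", "SM"): self.st_sm_min}

    def blood_half_times(self) -> dict[str, float | None]:
        return {"SV": self.sv_blood_min, "ST": self.st_blood_min,
                "SM": self.sm_blood_min}


@dataclass(frozen=True)
class PerfusionRoute:
    """Perfusion of one scala: flow enters at ``entry_mm`` and leaves at ``exit_mm``."""

    rate_ul_min: float
    inlet_conc_pct: float
    entry_mm: float
    exit_mm: float
    start_min: float = 0.0
    stop_min: float | None = None  # None = until end of run

    def __post_init__(self):
        if self.rate_ul_min < 0:
            raise ValidationError("perfusion rate must be >= 0")
        if not (0.0 <= self.inlet_conc_pct <= 100.0):
            raise ValidationError(
                f"inlet concentration must be in [0, 100], got {self.inlet_conc_pct}")
        if not self.entry_mm < self.exit_mm:
            raise ValidationError("perfusion entry must lie basal to exit")


@dataclass(frozen=True)
class PerfusionSpec:
    """Perfusion routes keyed by scala id (subset of SV, ST)."""

    routes: Mapping[str, PerfusionRoute] = field(default_factory=dict)

    def __post_init__(self):
        for scala in self.routes:
            if scala not in ("SV", "ST"):
                raise ValidationError(f"only SV and ST can be perfused, got {scala!r}")


@dataclass(frozen=True)
class ProbeSpec:
    scala: str
    x_mm: float

    @property
    def probe_id(self) -> str:
        return f"{self.scala}@{self.x_mm:g}mm"


@dataclass(frozen=True)
class SimulationConfig:
    diffusion_coeff_cm2_s: float = 2.3004e-5
    dx_mm: float = 0.1
    dt_s: float = 0.5
    duration_min: float = 120.0
    output_dt_min: float = 0.25
    probes: tuple[ProbeSpec, ...] = (ProbeSpec("SM", 1.0),
                                     ProbeSpec("SV", 1.0),
                                     ProbeSpec("ST", 1.0))

    def __post_init__(self):
        if self.diffusion_coeff_cm2_s <= 0:
            raise ValidationError("diffusion coefficient must be positive")
        if self.dx_mm <= 0 or self.dt_s <= 0 or self.duration_min <= 0:
            raise ValidationError("dx, dt and duration must be positive")
        if self.output_dt_min <= 0:
            raise ValidationError("output interval must be positive")


@dataclass(frozen=True)
class TimeCourse:
    """Concentration versus time at one probe position."""

    probe_id: str
    times_min: np.ndarray
    conc_pct: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times_min, dtype=float)
        c = np.asarray(self.conc_pct, dtype=float)
        if t.shape != c.shape:
            raise ValidationError("times and concentrations differ in length")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise ValidationError("times must be strictly increasing")
        object.__setattr__(self, "times_min", t)
        object.__setattr__(self, "conc_pct", c)


@dataclass(frozen=True)
class MassBalance:
    """Flux-accounted tracer bookkeeping over a run (units: %% * ul)."""

    inflow: float
    outflow: float
    cleared: float
    resident: float
    resident_initial: float

    @property
    def residual(self) -> float:
        return self.inflow + self.resident_initial - self.outflow - self.cleared - self.resident

    @property
    def relative_residual(self) -> float:
        scale = max(abs(self.inflow), abs(self.resident_initial), abs(self.resident), 1e-300)
        return abs(self.residual) / scale

    def to_dict(self) -> dict:
        return {"inflow": self.inflow, "outflow": self.outflow,
                "cleared": self.cleared, "resident": self.resident,
                "resident_initial": self.resident_initial,
                "relative_residual": self.relative_residual}


@dataclass(frozen=True)
class DispersalResult:
    timecourses: dict[str, TimeCourse]
    balance: MassBalance
    final_conc: dict[str, np.ndarray]
    grid_x_mm: dict[str, np.ndarray]
    config: SimulationConfig


class _ScalaState:
    """Grid, volumes and solver workspace for one scala."""

    def __init__(self, geom: ScalaGeometry, dx_mm: float, d_mm2_min: float):
        n = int(round(geom.length_mm / dx_mm)) + 1
        if n < 2:
            raise ValidationError(f"{geom.scala}: grid has fewer than 2 nodes")
        self.scala = geom.scala
        self.x = np.linspace(0.0, geom.length_mm, n)
        self.dx = geom.length_mm / (n - 1)
        self.area = geom.area_at(self.x)
        # node volumes (half cells at the ends)
        self.vol = self.area * self.dx
        self.vol[0] *= 0.5
        self.vol[-1] *= 0.5
        # diffusive interface conductances g_{i+1/2} = D * A_{i+1/2} / dx  (ul/min)
        a_face = 0.5 * (self.area[:-1] + self.area[1:])
        self.g = d_mm2_min * a_face / self.dx
        self.conc = np.zeros(n)
        self.n = n

    def node_index(self, x_mm: float, what: str) -> int:
        if not (0.0 <= x_mm <= self.x[-1] + 1e-9):
            raise ValidationError(
                f"{what} position {x_mm} mm outside {self.scala} domain "
                f"[0, {self.x[-1]:g}] mm")
        return int(round(x_mm / self.dx))

    def build_matrix(self, dt_min: float, route: PerfusionRoute | None):
        """Banded matrix and constant rhs pieces for one implicit step."""
        n = self.n
        lower = np.zeros(n)
        diag = self.vol / dt_min + np.zeros(n)
        upper = np.zeros(n)
        diag[:-1] += 0.5 * self.g
        diag[1:] += 0.5 * self.g
        upper[1:] = -0.5 * self.g          # column j=i+1 entry stored at ab[0, i+1]
        lower[:-1] = -0.5 * self.g         # column j=i-1 entry stored at ab[2, i-1]
        src = np.zeros(n)
        entry = exit_ = None
        q = 0.0
        if route is not None and route.rate_ul_min > 0:
            q = route.rate_ul_min
            entry = self.node_index(route.entry_mm, "perfusion entry")
            exit_ = self.node_index(route.exit_mm, "perfusion exit")
            diag[entry:exit_ + 1] += q
            lower[entry:exit_] -= q        # coupling of row i to node i-1
            src[entry] = q * route.inlet_conc_pct
        ab = np.zeros((3, n))
        ab[0] = upper
        ab[1] = diag
        ab[2] = lower
        return ab, src, entry, exit_, q


def _build_exchange_pairs(states: dict[str, _ScalaState],
                          comms: CommunicationSpec, dt_min: float):
    pairs = []
    for (a, b), t_half in comms.pair_half_times().items():
        if a not in states or b not in states:
            continue
        sa, sb = states[a], states[b]
        m = min(sa.n, sb.n)
        k = LN2 / t_half
        pairs.append((sa, sb, m, math.exp(-k * dt_min)))
    return pairs


def simulate_dispersal(geometries: Mapping[str, ScalaGeometry],
                       comms: CommunicationSpec,
                       perfusion: PerfusionSpec,
                       config: SimulationConfig,
                       initial_conc: Mapping[str, float] | None = None,
                       ) -> DispersalResult:
    """Run the coupled dispersal model and record probe time courses.

    ``initial_conc`` optionally seeds a uniform starting concentration
    per scala (default 0 everywhere).
    """
    d_mm2_min = config.diffusion_coeff_cm2_s * _CM2_S_TO_MM2_MIN
    dt_min = config.dt_s / 60.0
    states = {name: _ScalaState(geom, config.dx_mm, d_mm2_min)
              for name, geom in geometries.items()}
    if initial_conc:
        for name, c0 in initial_conc.items():
            if name not in states:
                raise ValidationError(f"initial concentration for unknown scala {name!r}")
            states[name].conc[:] = c0
    for scala in perfusion.routes:
        if scala not in states:
            raise ValidationError(f"perfused scala {scala!r} has no geometry")

    # probe bookkeeping
    probe_nodes = []
    for p in config.probes:
        if p.scala not in states:
            raise ValidationError(f"probe scala {p.scala!r} has no geometry")
        st = states[p.scala]
        if not (0.0 <= p.x_mm <= st.x[-1] + 1e-9):
            raise ValidationError(
                f"probe at {p.x_mm} mm outside {p.scala} domain [0, {st.x[-1]:g}] mm")
        probe_nodes.append((p.probe_id, st, p.x_mm))

    n_steps = int(round(config.duration_min / dt_min))
    out_every = max(1, int(round(config.output_dt_min / dt_min)))

    # per-scala solver setups for perfusion on/off
    setups = {}
    for name, st in states.items():
        route = perfusion.routes.get(name)
        on = st.build_matrix(dt_min, route)
        off = st.build_matrix(dt_min, None)
        setups[name] = (route, on, off)

    pairs = _build_exchange_pairs(states, comms, dt_min)
    blood = []
    for name, t_half in comms.blood_half_times().items():
        if name in states and t_half is not None:
            blood.append((states[name], math.exp(-(LN2 / t_half) * dt_min)))

    inflow = outflow = cleared = 0.0
    resident0 = sum(float(st.vol @ st.conc) for st in states.values())

    times = [0.0]
    records = {pid: [float(np.interp(x, st.x, st.conc))] for pid, st, x in probe_nodes}

    for step in range(1, n_steps + 1):
        t_prev = (step - 1) * dt_min
        # 1) diffusion (CN) + advection (BE, conservative upwind), one solve per scala
        for name, st in states.items():
            route, on, off = setups[name]
            active = (route is not None and route.rate_ul_min > 0
                      and route.start_min <= t_prev
                      and (route.stop_min is None or t_prev < route.stop_min))
            ab, src, entry, exit_, q = on if active else off
            c = st.conc
            rhs = st.vol / dt_min * c + src
            rhs[:-1] += 0.5 * st.g * (c[1:] - c[:-1])
            rhs[1:] += 0.5 * st.g * (c[:-1] - c[1:])
            c_new = solve_banded((1, 1), ab, rhs, check_finite=False)
            st.conc = c_new
            if active:
                inflow += src[entry] * dt_min
                outflow += q * c_new[exit_] * dt_min
        # 2) exact pairwise exchange (mass conserving)
        for sa, sb, m, decay in pairs:
            va, vb = sa.vol[:m], sb.vol[:m]
            ca, cb = sa.conc[:m], sb.conc[:m]
            ceq = (va * ca + vb * cb) / (va + vb)
            sa.conc[:m] = ceq + (ca - ceq) * decay
            sb.conc[:m] = ceq + (cb - ceq) * decay
        # 3) blood clearance (exact exponential), with cleared-mass accounting
        for st, factor in blood:
            cleared += float(st.vol @ st.conc) * (1.0 - factor)
            st.conc *= factor
        if step % out_every == 0:
            times.append(step * dt_min)
            for pid, st, x in probe_nodes:
                records[pid].append(float(np.interp(x, st.x, st.conc)))

    resident = sum(float(st.vol @ st.conc) for st in states.values())
    balance = MassBalance(inflow=inflow, outflow=outflow, cleared=cleared,
                          resident=resident, resident_initial=resident0)
    t_arr = np.asarray(times)
    tcs = {pid: TimeCourse(pid, t_arr, np.asarray(vals))
           for pid, vals in records.items()}
    return DispersalResult(timecourses=tcs, balance=balance,
                           final_conc={n: s.conc.copy() for n, s in states.items()},
                           grid_x_mm={n: s.x.copy() for n, s in states.items()},
                           config=config)


def probe(tc: TimeCourse, t_min: float) -> float:
    """Linearly interpolated concentration at time ``t_min``."""
    t = tc.times_min
    slack = 1e-9 * max(1.0, abs(t[-1]))  # guard against fp accumulation in the grid
    if not (t[0] - slack <= t_min <= t[-1] + slack):
        raise ValidationError(
            f"time {t_min} min outside simulated range [{t[0]:g}, {t[-1]:g}] min")
    return float(np.interp(t_min, t, tc.conc_pct))


def mass_balance(result: DispersalResult) -> MassBalance:
    return result.balance


@dataclass(frozen=True)
class CalibrationResult:
    half_time_min: float
    achieved_conc_pct: float
    target_conc_pct: float
    converged: bool
    unreachable: bool
    n_evaluations: int


_COMM_FIELDS = {"sv_sm": "sv_sm_min", "st_sv": "st_sv_min", "st_sm": "st_sm_min",
                "sv_blood": "sv_blood_min", "st_blood": "st_blood_min",
                "sm_blood": "sm_blood_min"}


def calibrate_half_time(geometries: Mapping[str, ScalaGeometry],
                        comms: CommunicationSpec,
                        perfusion: PerfusionSpec,
                        config: SimulationConfig,
                        target: tuple[str, float, float],
                        which: str,
                        bracket: tuple[float, float] = (0.05, BLOCKED_HALF_TIME_MIN),
                        rel_tol: float = 1e-3,
                        max_iter: int = 60) -> CalibrationResult:
    """Bisection on log(t_half) until the probe hits a target concentration.

    ``target`` is ``(probe_id, time_min, concentration_pct)``; ``which``
    names the communication to tune (e.g. ``"sv_sm"``).  Probe
    concentration is monotone decreasing in any half-time feeding the
    probed scala, which bisection relies on.  A target of 0 (or below
    what the slowest exchange yields) returns the upper bracket bound
    flagged unreachable; a target above what the fastest exchange yields
    raises :class:`CalibrationError` reporting both endpoint values.
    """
    if which not in _COMM_FIELDS:
        raise ValidationError(
            f"unknown communication {which!r}; expected one of {sorted(_COMM_FIELDS)}")
    probe_id, t_target, c_target = target
    lo, hi = bracket
    if not (0 < lo < hi):
        raise ValidationError("bracket must satisfy 0 < lo < hi")
    run_cfg = replace(config, duration_min=t_target,
                      output_dt_min=min(config.output_dt_min, t_target / 4))
    n_evals = 0

    def run(t_half: float) -> float:
        nonlocal n_evals
        n_evals += 1
        c = replace(comms, **{_COMM_FIELDS[which]: t_half})
        res = simulate_dispersal(geometries, c, perfusion, run_cfg)
        if probe_id not in res.timecourses:
            raise ValidationError(f"unknown probe {probe_id!r}; "
                                  f"have {sorted(res.timecourses)}")
        return probe(res.timecourses[probe_id], t_target)

    f_lo = run(lo)   # fastest exchange -> highest concentration
    f_hi = run(hi)   # slowest exchange -> lowest concentration
    if c_target > f_lo:
        raise CalibrationError(
            f"target {c_target} above achievable range: bracket endpoints give "
            f"{f_hi:.6g} (t_half={hi}) .. {f_lo:.6g} (t_half={lo})",
            lo_value=f_lo, hi_value=f_hi)
    if c_target <= f_hi:
        return CalibrationResult(half_time_min=hi, achieved_conc_pct=f_hi,
                                 target_conc_pct=c_target, converged=False,
                                 unreachable=True, n_evaluations=n_evals)
    log_lo, log_hi = math.log(lo), math.log(hi)
    mid = 0.5 * (log_lo + log_hi)
    f_mid = run(math.exp(mid))
    for _ in range(max_iter):
        if abs(f_mid - c_target) <= rel_tol * abs(c_target):
            break
        if f_mid > c_target:
            log_lo = mid      # too fast -> lengthen half-time
        else:
            log_hi = mid
        mid = 0.5 * (log_lo + log_hi)
        f_mid = run(math.exp(mid))
    converged = abs(f_mid - c_target) <= rel_tol * abs(c_target)
    return CalibrationResult(half_time_min=math.exp(mid), achieved_conc_pct=f_mid,
                             target_conc_pct=c_target, converged=converged,
                             unreachable=False, n_evaluations=n_evals)
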