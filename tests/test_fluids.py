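import math
from dataclasses import replace

import numpy as np
import pytest

from cochperm.errors import CalibrationError, ValidationError
from cochperm.fluids import (BLOCKED_HALF_TIME_MIN, CommunicationSpec,
                             PerfusionRoute, PerfusionSpec, ProbeSpec,
                             ScalaGeometry, SimulationConfig, TimeCourse,
                             calibrate_half_time, default_geometries,
                             mass_balance, probe, simulate_dispersal)
from cochperm.scenarios import load_scenario

LN2 = math.log(2.0)


def run_scenario(name, config=None, comms=None):
    spec = load_scenario(name)
    return simulate_dispersal(spec.geometries, comms or spec.comms,
                              spec.perfusion, config or spec.config)


class TestGeometry:
    def test_default_dimensions(self):
        geos = default_geometries()
        assert geos["SV"].length_mm == 15.5
        assert geos["ST"].length_mm == 16.2
        assert geos["SM"].volume_ul == pytest.approx(1.2, rel=1e-9)

    def test_nonpositive_area_rejected(self):
        with pytest.raises(ValidationError):
            ScalaGeometry("SV", 10.0, (0.0, 10.0), (1.0, 0.0))


class TestSimulateDispersal:
    def test_zero_inlet_stays_zero(self, coarse_config):
        spec = load_scenario("SV+ST/SM")
        routes = {k: replace(r, inlet_conc_pct=0.0)
                  for k, r in spec.perfusion.routes.items()}
        res = simulate_dispersal(spec.geometries, spec.comms,
                                 PerfusionSpec(routes), coarse_config)
        for tc in res.timecourses.values():
            assert np.all(tc.conc_pct == 0.0)

    def test_mass_balance_under_steady_perfusion(self, coarse_config):
        res = run_scenario("SV+ST/SM", config=coarse_config)
        assert res.balance.relative_residual <= 1e-3
        # scheme is conservative to round-off, well below the contract
        assert res.balance.relative_residual <= 1e-10

    def test_concentrations_bounded(self, coarse_config):
        res = run_scenario("SV+ST/SM", config=coarse_config)
        for tc in res.timecourses.values():
            assert np.all(tc.conc_pct >= -1e-9)
            assert np.all(tc.conc_pct <= 100.0 + 1e-9)

    def test_closed_system_conserves_resident_mass(self, two_compartments):
        geometries, comms, config = two_compartments
        res = simulate_dispersal(geometries, comms, PerfusionSpec(), config,
                                 initial_conc={"SV": 100.0})
        bal = mass_balance(res)
        assert bal.inflow == 0.0 and bal.outflow == 0.0 and bal.cleared == 0.0
        assert bal.resident == pytest.approx(bal.resident_initial, rel=1e-6)

    def test_two_compartment_closed_form(self, two_compartments):
        geometries, comms, config = two_compartments
        res = simulate_dispersal(geometries, comms, PerfusionSpec(), config,
                                 initial_conc={"SV": 100.0})
        for t in (1.0, 2.0, 5.0, 10.0):
            diff = (probe(res.timecourses["SV@0.1mm"], t)
                    - probe(res.timecourses["SM@0.1mm"], t))
            assert diff == pytest.approx(100.0 * math.exp(-LN2 * t / 2.2),
                                         rel=0.01)

    def test_blood_clearance_quadrature(self):
        geometries = {"SM": ScalaGeometry.uniform("SM", 1.0, 1.2)}
        comms = CommunicationSpec(sv_blood_min=None, st_blood_min=None,
                                  sm_blood_min=15.0)
        config = SimulationConfig(dx_mm=0.2, dt_s=1.0, duration_min=30.0,
                                  output_dt_min=1.0, probes=(ProbeSpec("SM", 0.5),))
        res = simulate_dispersal(geometries, comms, PerfusionSpec(), config,
                                 initial_conc={"SM": 100.0})
        bal = res.balance
        # cleared + resident stays equal to the initial mass
        assert bal.cleared + bal.resident == pytest.approx(bal.resident_initial,
                                                           rel=1e-9)
        # pure exponential decay of the resident mass
        expected = bal.resident_initial * math.exp(-LN2 * 30.0 / 15.0)
        assert bal.resident == pytest.approx(expected, rel=1e-9)

    def test_blocked_exchange_keeps_st_clean(self, coarse_config):
        # one perilymphatic scala carries tracer; the other is rinsed and
        # only communicates through the 9,999-min channel
        res = run_scenario("SV/SM", config=coarse_config)
        st_10 = probe(res.timecourses["ST@1mm"], 10.0)
        sv_10 = probe(res.timecourses["SV@1mm"], 10.0)
        assert st_10 < 0.02 * sv_10

    def test_blocked_exchange_leakage_negligible(self, coarse_config):
        config = replace(coarse_config, duration_min=120.0, output_dt_min=2.0)
        res_sentinel = run_scenario("SV/SM", config=config)
        spec = load_scenario("SV/SM")
        comms_off = replace(spec.comms, st_sv_min=1e15)
        res_off = run_scenario("SV/SM", config=config, comms=comms_off)
        for pid in res_sentinel.timecourses:
            delta = np.max(np.abs(res_sentinel.timecourses[pid].conc_pct
                                  - res_off.timecourses[pid].conc_pct))
            assert delta < 0.1  # % of perfusate

    def test_grid_refinement(self):
        spec = load_scenario("SV+ST/SM")
        vals = {}
        for dx in (0.2, 0.1):
            config = replace(spec.config, dx_mm=dx, duration_min=7.0,
                             output_dt_min=0.25)
            res = simulate_dispersal(spec.geometries, spec.comms,
                                     spec.perfusion, config)
            vals[dx] = probe(res.timecourses["SM@1mm"], 7.0)
        assert abs(vals[0.1] - vals[0.2]) / vals[0.1] < 0.005

    def test_monotone_in_feeding_half_time(self, coarse_config):
        spec = load_scenario("SV+ST/SM")
        config = replace(coarse_config, duration_min=7.0)
        out = []
        for t_half in (1.1, 2.2, 4.4, 8.8):
            comms = replace(spec.comms, sv_sm_min=t_half)
            res = simulate_dispersal(spec.geometries, comms, spec.perfusion,
                                     config)
            out.append(probe(res.timecourses["SM@1mm"], 7.0))
        assert all(a > b for a, b in zip(out, out[1:]))

    def test_probe_outside_domain_rejected(self, coarse_config):
        spec = load_scenario("SV+ST/SM")
        config = replace(coarse_config,
                         probes=(ProbeSpec("SM", 99.0),))
        with pytest.raises(ValidationError, match="probe"):
            simulate_dispersal(spec.geometries, spec.comms, spec.perfusion,
                               config)


class TestProbe:
    def make_tc(self):
        return TimeCourse("SM@1mm", np.array([0.0, 10.0, 20.0]),
                          np.array([0.0, 10.0, 20.0]))

    def test_stored_node(self):
        assert probe(self.make_tc(), 10.0) == 10.0

    def test_equal_neighbours(self):
        tc = TimeCourse("p", np.array([0.0, 10.0]), np.array([7.0, 7.0]))
        assert probe(tc, 5.0) == 7.0

    def test_midway_linear(self):
        assert probe(self.make_tc(), 15.0) == pytest.approx(15.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            probe(self.make_tc(), 21.0)

    def test_nonmonotone_times_rejected(self):
        with pytest.raises(ValidationError):
            TimeCourse("p", np.array([0.0, 2.0, 1.0]), np.zeros(3))


class TestCalibration:
    @pytest.fixture
    def cal_setup(self, coarse_config):
        spec = load_scenario("SV+ST/SM")
        config = replace(coarse_config, duration_min=7.0)
        return spec, config

    def test_round_trip_recovers_half_time(self, cal_setup):
        spec, config = cal_setup
        forward = simulate_dispersal(spec.geometries, spec.comms,
                                     spec.perfusion, config)
        target_conc = probe(forward.timecourses["SM@1mm"], 7.0)
        cal = calibrate_half_time(spec.geometries, spec.comms, spec.perfusion,
                                  config, target=("SM@1mm", 7.0, target_conc),
                                  which="sv_sm", bracket=(0.2, 50.0))
        assert cal.converged and not cal.unreachable
        assert cal.half_time_min == pytest.approx(2.2, rel=0.01)

    def test_zero_target_unreachable(self, cal_setup):
        spec, config = cal_setup
        cal = calibrate_half_time(spec.geometries, spec.comms, spec.perfusion,
                                  config, target=("SM@1mm", 7.0, 0.0),
                                  which="sv_sm", bracket=(0.2, 50.0))
        assert cal.unreachable
        assert cal.half_time_min == 50.0

    def test_overshooting_target_raises_with_endpoints(self, cal_setup):
        spec, config = cal_setup
        with pytest.raises(CalibrationError) as excinfo:
            calibrate_half_time(spec.geometries, spec.comms, spec.perfusion,
                                config, target=("SM@1mm", 7.0, 99.999),
                                which="sv_sm", bracket=(1.0, 50.0))
        assert excinfo.value.lo_value is not None
        assert excinfo.value.hi_value is not None

    def test_unknown_communication_rejected(self, cal_setup):
        spec, config = cal_setup
        with pytest.raises(ValidationError, match="communication"):
            calibrate_half_time(spec.geometries, spec.comms, spec.perfusion,
                                config, target=("SM@1mm", 7.0, 10.0),
                                which="sm_sv")
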