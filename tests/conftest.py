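import numpy as np
import pytest

from cochperm import morphometry
from cochperm.fluids import (CommunicationSpec, PerfusionRoute, PerfusionSpec,
                             ProbeSpec, ScalaGeometry, SimulationConfig)

#: Rate-constant triples (P', P'', alpha) of the three simulated models
#: plus the in vivo reference column.
TABLE3_TRIPLES = {
    "SV/SM": (0.691, 0.938, 0.504),
    "ST/SM": (0.499, 0.940, 0.435),
    "SV+ST/SM": (0.869, 0.898, 0.549),
    "in_vivo": (0.85, 0.9, 0.4),
}


@pytest.fixture(scope="session")
def fixture_table():
    return morphometry.default_half_turn_table()


@pytest.fixture
def two_compartments():
    """Two short well-mixed tubes coupled only via the SV-SM channel."""
    geometries = {
        "SV": ScalaGeometry.uniform("SV", 0.2, 0.5),
        "SM": ScalaGeometry.uniform("SM", 0.2, 0.3),
    }
    comms = CommunicationSpec(sv_sm_min=2.2, st_sv_min=9999.0, st_sm_min=9999.0,
                              sv_blood_min=None, st_blood_min=None,
                              sm_blood_min=None)
    config = SimulationConfig(dx_mm=0.1, dt_s=0.5, duration_min=10.0,
                              output_dt_min=0.1,
                              probes=(ProbeSpec("SV", 0.1), ProbeSpec("SM", 0.1)))
    return geometries, comms, config


@pytest.fixture
def coarse_config():
    """Coarsened grid for fast simulator tests."""
    return SimulationConfig(dx_mm=0.2, dt_s=1.0, duration_min=10.0,
                            output_dt_min=0.25,
                            probes=(ProbeSpec("SM", 1.0), ProbeSpec("SV", 1.0),
                                    ProbeSpec("ST", 1.0)))
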