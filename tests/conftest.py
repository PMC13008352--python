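"""Shared fixtures: scenario runs at the published parameter points.

The forward simulations are session-scoped because several tests (and the
acceptance suite) interrogate the same run.
"""

import numpy as np
import pytest

from porocell import (
    IndentationProtocol,
    MaterialRegion,
    PressureProtocol,
    ScenarioGeometry,
    simulate_depressurisation,
    simulate_indentation,
    simulate_injection,
)

# published fit points: indentation E = 1.8 kPa / D = 28 um^2/s,
# injection E = 1.2 kPa / D = 13 um^2/s at P_eff = 500 Pa
E_INDENT, D_INDENT = 1800.0, 28.0
E_INJECT, D_INJECT = 1200.0, 13.0
P_EFF = 500.0


@pytest.fixture(scope="session")
def disk_geometry():
    return ScenarioGeometry("disk", radius=20.0, thickness=20.0, indenter_radius=2.0)


@pytest.fixture(scope="session")
def thin_disk_geometry():
    # disk of the experimental (spread-cell) thickness
    return ScenarioGeometry("disk", radius=20.0, thickness=4.5, indenter_radius=2.0)


@pytest.fixture(scope="session")
def cap_geometry():
    return ScenarioGeometry(
        "elliptical_cap", radius=20.0, thickness=4.5, contact_or_sink_radius=1.0
    )


@pytest.fixture(scope="session")
def cap_geometry_cortex():
    return ScenarioGeometry(
        "elliptical_cap", radius=20.0, thickness=4.5,
        cortex_thickness=0.25, contact_or_sink_radius=1.0,
    )


@pytest.fixture(scope="session")
def cyto_indent():
    return MaterialRegion("cytoplasm", E=E_INDENT, nu=0.3, D=D_INDENT)


@pytest.fixture(scope="session")
def cyto_inject():
    return MaterialRegion("cytoplasm", E=E_INJECT, nu=0.3, D=D_INJECT)


@pytest.fixture(scope="session")
def indentation_response(disk_geometry, cyto_indent):
    protocol = IndentationProtocol(depth=2.0, ramp_time=0.01, hold_time=30.0)
    return simulate_indentation(
        disk_geometry, [cyto_indent], protocol, probes=np.linspace(3.0, 16.0, 10)
    )


@pytest.fixture(scope="session")
def thin_indentation_response(thin_disk_geometry, cyto_indent):
    protocol = IndentationProtocol(depth=2.0, ramp_time=0.01, hold_time=60.0)
    return simulate_indentation(
        thin_disk_geometry, [cyto_indent], protocol,
        probes=np.linspace(3.0, 16.0, 10), resolution=1.5, n_z=6,
    )


@pytest.fixture(scope="session")
def injection_response(cap_geometry, cyto_inject):
    protocol = PressureProtocol(
        P_in=0.0, P_app=P_EFF, ramp_time=2.0, duration=40.0, mode="injection"
    )
    return simulate_injection(
        cap_geometry, [cyto_inject], protocol, probes=np.linspace(3.0, 15.0, 7)
    )


@pytest.fixture(scope="session")
def depressurisation_sweep(cap_geometry_cortex, cyto_inject):
    cortex = MaterialRegion("cortex", E=E_INJECT, nu=0.3, D=0.1)
    protocol = PressureProtocol(
        P_in=500.0, P_app=0.0, ramp_time=0.1, duration=60.0, mode="release"
    )
    return simulate_depressurisation(
        cap_geometry_cortex, [cyto_inject, cortex], protocol,
        D1_sweep=np.array([0.01, 0.1, 1.0, 10.0]),
    )
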