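"""Shared fixtures.

The 11-subject control group is expensive (it runs the full pipeline on
eleven 120-stimulus sessions), so it is computed once per test session
and shared between the network-level tests and the acceptance suite.
"""

import numpy as np
import pytest

import tvnet

CONTROL_SEEDS = tuple(range(1, 12))


@pytest.fixture(scope="session")
def default_config():
    return tvnet.PipelineConfig()


@pytest.fixture(scope="session")
def control_sessions():
    return [tvnet.make_tms_session_fixture("control", seed=s) for s in CONTROL_SEEDS]


@pytest.fixture(scope="session")
def control_results(control_sessions, default_config):
    return [tvnet.run_subject(default_config, s) for s in control_sessions]


@pytest.fixture(scope="session")
def control_group_corrected(control_results):
    return tvnet.group_average([r.corrected for r in control_results])


@pytest.fixture(scope="session")
def small_control_result():
    """One 20-stimulus control subject through the default pipeline."""
    session = tvnet.make_tms_session_fixture("control", seed=42, n_events=20)
    return session, tvnet.run_subject(tvnet.PipelineConfig(), session)


@pytest.fixture(scope="session")
def two_node_system():
    """Stationary 2-channel order-1 system with a single 1 -> 2 coupling."""
    return tvnet.make_tv_system(
        2, couplings=[tvnet.Coupling(0, 1, 0.4)], order=1, diag=0.5,
        window_ms=(0.0, 20000.0),
    )
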