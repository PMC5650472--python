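import warnings

import numpy as np
import pytest

from gapclosure.synthetic_cells import (
    CellSpec,
    SessionDesign,
    generate_session,
)
from gapclosure.task_kinematics import TaskConfig, gait_timeline, gap_trace

warnings.filterwarnings("ignore", category=UserWarning, module="gapclosure")


@pytest.fixture(scope="session")
def matched_config() -> TaskConfig:
    return TaskConfig()


@pytest.fixture(scope="session")
def vd_config() -> TaskConfig:
    return TaskConfig(obstacle_speed=0.3)


@pytest.fixture(scope="session")
def matched_gap(matched_config):
    timeline = gait_timeline(matched_config, n_steps=12, jitter_sd=0.0, lead_limb="left")
    return gap_trace(matched_config, timeline, initial_dtc=200.0)


@pytest.fixture(scope="session")
def vd_gap(vd_config):
    timeline = gait_timeline(vd_config, n_steps=12, jitter_sd=0.0, lead_limb="left")
    return gap_trace(vd_config, timeline, initial_dtc=200.0)


@pytest.fixture(scope="session")
def small_session():
    """One DTC, one TTC and one untuned cell with modest trial counts."""
    specs = [
        CellSpec(cell_id="dtc", category="DTC", trigger_dtc_cm=30.0, onset_jitter_sd=50.0),
        CellSpec(
            cell_id="ttc", category="TTC", trigger_dtc_cm=None,
            trigger_ttc_ms=600.0, onset_jitter_sd=50.0,
        ),
        CellSpec(cell_id="none", category="NONE", trigger_dtc_cm=None),
    ]
    design = SessionDesign(
        n_matched_per_lead=10, n_vd_per_lead=10, accel_conditions=(), n_unobstructed=5
    )
    return generate_session(specs, design, seed=1234)
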