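import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from openlook.openface_io import SessionTable, column_groups, session_from_arrays
from openlook.protocol import default_maap_protocol
from openlook.simulate import SimConfig, simulate_session

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_gaze_table(
    confidence,
    success=None,
    fps: float = 10.0,
    yaw=None,
    pitch=None,
    **kwargs,
) -> SessionTable:
    """Minimal gaze-only session table for unit tests."""
    conf = np.asarray(confidence, dtype=float)
    n = conf.size
    succ = np.ones(n, dtype=int) if success is None else np.asarray(success, dtype=int)
    yaw = np.zeros(n) if yaw is None else np.asarray(yaw, dtype=float)
    pitch = np.zeros(n) if pitch is None else np.asarray(pitch, dtype=float)
    vx = np.sin(yaw) * np.cos(pitch)
    vy = np.sin(pitch)
    vz = -np.cos(yaw) * np.cos(pitch)
    feats = {
        "gaze_0_x": vx, "gaze_0_y": vy, "gaze_0_z": vz,
        "gaze_1_x": vx, "gaze_1_y": vy, "gaze_1_z": vz,
        "gaze_angle_x": yaw, "gaze_angle_y": pitch,
    }
    return session_from_arrays(
        timestamps=np.arange(n) / fps,
        confidence=conf,
        success=succ,
        features=feats,
        fps=fps,
        **kwargs,
    )


@pytest.fixture(scope="session")
def short_sim_config() -> SimConfig:
    """Calibration plus four short trials; small enough for unit tests."""
    return SimConfig(protocol=default_maap_protocol(n_trials=4, block_size=2))


@pytest.fixture(scope="session")
def short_session(short_sim_config):
    return simulate_session(short_sim_config, seed=123)


@pytest.fixture(scope="session")
def full_feature_columns():
    cols = []
    for group in column_groups().values():
        cols.extend(group)
    return cols
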