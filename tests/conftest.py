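import numpy as np
import pytest

from reachkin.kinematic_metrics import SpeedThresholds
from reachkin.records import TrialRecord
from reachkin.synthetic_cohort import (
    ImpairmentProfile,
    joint_angles_from_hand,
    minimum_jerk_reach,
)
from reachkin.task_protocol import Direction, TaskConfig


@pytest.fixture(scope="session")
def config() -> TaskConfig:
    return TaskConfig()


@pytest.fixture(scope="session")
def fast_config() -> TaskConfig:
    """Short-hold, short-session variant for tests that need many trials;
    the hold still exceeds the 500-ms threshold window."""
    return TaskConfig(hold_min=550, hold_max=700, n_trials=16)


def make_trial(
    hand_xy: np.ndarray,
    target: Direction | None = Direction.F,
    target_onset_ms: int | None = None,
    left_center: bool = True,
    reached: bool = True,
    reach_duration_ms: int | None = None,
    recorded_arm: str = "left",
    with_angles: bool = True,
) -> TrialRecord:
    """Assemble a TrialRecord around a hand path, deriving joint angles."""
    hand_xy = np.asarray(hand_xy, dtype=float)
    n = hand_xy.shape[0]
    if with_angles:
        sh, el = joint_angles_from_hand(hand_xy)
    else:
        sh = np.zeros(n)
        el = np.zeros(n)
    return TrialRecord(
        trial_index=0,
        target=target,
        t_ms=np.arange(n),
        hand_xy=hand_xy,
        shoulder_deg=sh,
        elbow_deg=el,
        target_onset_ms=target_onset_ms,
        left_center=left_center,
        reached_target=reached,
        reach_duration_ms=reach_duration_ms,
        recorded_arm=recorded_arm,
    )


def noiseless_reach_trial(
    direction: Direction = Direction.F,
    hold_ms: int = 1300,
    duration_ms: int = 800,
    config: TaskConfig = TaskConfig(),
    r_fin: float = 0.3,
) -> TrialRecord:
    """Hold at the centre then a single clean minimum-jerk reach."""
    from reachkin.task_protocol import direction_unit_vector

    tgt = config.target_distance * direction_unit_vector(direction)
    end = tgt - r_fin * tgt / np.hypot(*tgt)
    reach = minimum_jerk_reach((0.0, 0.0), end, duration_ms)
    hold = np.tile((0.0, 0.0), (hold_ms, 1))
    pos = np.vstack([hold, reach])
    pos = np.round(pos / config.spatial_resolution) * config.spatial_resolution
    return make_trial(
        pos,
        target=direction,
        target_onset_ms=hold_ms,
        reached=True,
        reach_duration_ms=duration_ms,
    )


@pytest.fixture
def zero_thresholds() -> SpeedThresholds:
    return SpeedThresholds(0.0, 0.0)


def unimpaired_profile(**overrides) -> ImpairmentProfile:
    defaults = dict(
        completion_prob=1.0,
        time_scale=1.0,
        ap_gain=0.0,
        extra_submovements=0.0,
        hold_failure_prob=0.0,
        noise_sd=0.0,
    )
    defaults.update(overrides)
    return ImpairmentProfile.from_scalars(**defaults)
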