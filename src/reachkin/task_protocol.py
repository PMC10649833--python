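"""Geometry, timing, and clinical-severity conventions of the reaching task.

The task is a planar, gravity-supported center-out reach: the hand cursor
(a 0.4-cm circle) is held inside a central target (1.0-cm circle) for a
randomized hold period, after which one of eight peripheral targets
(1.0-cm circles, 10 cm from the centre, every 45°) is illuminated and the
participant reaches for it within 3,000 ms.  Sessions recorded with the
right arm are mirrored into a common left-arm frame before analysis.

Coordinate convention (left-arm frame): ``+x`` points toward the
participant's midline ("medial"), ``+y`` points away from the body
("forward").  Direction labels are body-referenced, so mirroring flips
coordinates but leaves labels untouched.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace
from typing import List, Tuple

import numpy as np

from .records import TrialRecord

__all__ = [
    "Direction",
    "DIRECTION_ORDER",
    "TaskConfig",
    "SeverityLevel",
    "SeverityGroup",
    "Severity",
    "classify_severity",
    "target_positions",
    "direction_unit_vector",
    "mirror_x",
    "mirror_to_left",
]


class Direction(enum.Enum):
    """The eight aiming directions, named relative to the participant's body."""

    M = "M"    # medial
    MF = "MF"  # medial forward
    F = "F"    # forward
    LF = "LF"  # lateral forward
    L = "L"    # lateral
    LB = "LB"  # lateral backward
    B = "B"    # backward
    MB = "MB"  # medial backward

    @property
    def angle_deg(self) -> float:
        """Angle in the left-arm frame; M is along +x, F along +y."""
        return 45.0 * DIRECTION_ORDER.index(self)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


DIRECTION_ORDER: List[Direction] = [
    Direction.M,
    Direction.MF,
    Direction.F,
    Direction.LF,
    Direction.L,
    Direction.LB,
    Direction.B,
    Direction.MB,
]

_SQ2 = math.sqrt(2.0) / 2.0
# Exact unit vectors for multiples of 45 degrees (avoids cos/sin rounding on
# the axis-aligned directions).
_UNIT = {
    Direction.M: (1.0, 0.0),
    Direction.MF: (_SQ2, _SQ2),
    Direction.F: (0.0, 1.0),
    Direction.LF: (-_SQ2, _SQ2),
    Direction.L: (-1.0, 0.0),
    Direction.LB: (-_SQ2, -_SQ2),
    Direction.B: (0.0, -1.0),
    Direction.MB: (_SQ2, -_SQ2),
}


def direction_unit_vector(direction: Direction) -> np.ndarray:
    """Unit vector of a direction label in the left-arm frame."""
    return np.array(_UNIT[direction], dtype=float)


@dataclass(frozen=True)
class TaskConfig:
    """Constants of the visually guided reaching protocol.

    Defaults are the protocol as administered: 8 targets on a 10-cm circle,
    1-cm target radii, 0.4-cm cursor, a 1,250-1,750-ms randomized hold,
    a 3,000-ms reach limit and 5,000-ms return limit, 64 trials per session,
    sampled at 1 kHz with 0.01-cm spatial resolution.
    """

    n_targets: int = 8
    target_distance: float = 10.0
    central_radius: float = 1.0
    peripheral_radius: float = 1.0
    cursor_radius: float = 0.4
    hold_min: int = 1250
    hold_max: int = 1750
    reach_limit: int = 3000
    return_limit: int = 5000
    n_trials: int = 64
    sample_rate: float = 1000.0
    spatial_resolution: float = 0.01

    def __post_init__(self) -> None:
        if self.n_targets != len(DIRECTION_ORDER):
            raise ValueError("the protocol defines exactly 8 aiming directions")
        for name in (
            "target_distance",
            "central_radius",
            "peripheral_radius",
            "cursor_radius",
            "sample_rate",
            "spatial_resolution",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not self.hold_min < self.hold_max:
            raise ValueError("hold_min must be strictly less than hold_max")
        if self.reach_limit <= 0 or self.return_limit <= 0:
            raise ValueError("time limits must be positive")
        if self.n_trials <= 0 or self.n_trials % self.n_targets != 0:
            raise ValueError("n_trials must be a positive multiple of n_targets")
        if self.target_distance <= self.central_radius + self.peripheral_radius:
            raise ValueError("peripheral targets must not overlap the central target")

    @property
    def exit_radius(self) -> float:
        """Centre distance at which the cursor is deemed to have left the
        central target (cursor no longer contained in the centre circle)."""
        return self.central_radius + self.cursor_radius


def target_positions(config: TaskConfig) -> List[Tuple[Direction, np.ndarray]]:
    """Peripheral target centres in the left-arm frame, ordered M..MB.

    Every point lies ``config.target_distance`` from the origin with exact
    45° spacing; M is along +x and F along +y.
    """
    return [
        (d, config.target_distance * direction_unit_vector(d))
        for d in DIRECTION_ORDER
    ]


class SeverityLevel(str, enum.Enum):
    MILD = "mild"
    MODERATE = "moderate"
    SEVERE = "severe"


class SeverityGroup(str, enum.Enum):
    MILD = "mild"
    MODERATE_TO_SEVERE = "moderate_to_severe"


@dataclass(frozen=True)
class Severity:
    level: SeverityLevel
    group: SeverityGroup


def classify_severity(fma_ue: int) -> Severity:
    """Classify a Fugl-Meyer upper-extremity score (0-66 integer).

    Scores above 45 are mild; 30-45 moderate; below 30 severe.  Moderate and
    severe levels are pooled into the moderate-to-severe analysis group.
    Non-integer or out-of-range scores are rejected rather than rounded.
    """
    if isinstance(fma_ue, bool):
        raise TypeError("FMA-UE score must be an integer, not a bool")
    if isinstance(fma_ue, float):
        if not float(fma_ue).is_integer():
            raise ValueError(f"FMA-UE score must be an integer, got {fma_ue!r}")
        fma_ue = int(fma_ue)
    score = int(fma_ue)
    if score != fma_ue:
        raise ValueError(f"FMA-UE score must be an integer, got {fma_ue!r}")
    if not 0 <= score <= 66:
        raise ValueError(f"FMA-UE score must lie in 0..66, got {score}")
    if score > 45:
        level = SeverityLevel.MILD
    elif score >= 30:
        level = SeverityLevel.MODERATE
    else:
        level = SeverityLevel.SEVERE
    group = (
        SeverityGroup.MILD
        if level is SeverityLevel.MILD
        else SeverityGroup.MODERATE_TO_SEVERE
    )
    return Severity(level=level, group=group)


def mirror_x(trial: TrialRecord) -> TrialRecord:
    """Reflect a trial about the mediolateral zero of its start position.

    This is an exact involution: x coordinates are negated about the centre,
    y is untouched, and the recorded-arm flag is toggled.  Direction labels
    are body-referenced (M stays "toward the midline") and therefore do not
    change.
    """
    cx = float(trial.center_xy[0])
    hand = trial.hand_xy.copy()
    hand[:, 0] = 2.0 * cx - hand[:, 0]
    return replace(
        trial,
        hand_xy=hand,
        recorded_arm="left" if trial.recorded_arm == "right" else "right",
    )


def mirror_to_left(trial: TrialRecord) -> TrialRecord:
    """Express a trial in the common left-arm frame.

    Left-arm recordings are returned unchanged; right-arm recordings are
    reflected with :func:`mirror_x`.  The operation is idempotent.
    """
    if trial.recorded_arm == "left":
        return trial
    return mirror_x(trial)
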