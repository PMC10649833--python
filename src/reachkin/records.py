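"""Shared in-memory containers for trials and sessions.

A :class:`TrialRecord` stores one trial's per-millisecond hand path and
joint angles together with the event annotations that the qualification
rules and metric extractors consume.  A :class:`ParticipantSession` is one
participant x side x timepoint block of scheduled trials plus the clinical
score recorded at that timepoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple, TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .task_protocol import Direction

__all__ = ["TrialRecord", "ParticipantSession"]


@dataclass
class TrialRecord:
    """One trial: per-millisecond kinematics plus outcome annotations.

    ``target`` is ``None`` when the trial counter advanced without a target
    being shown (hold failure).  ``target_onset_ms`` indexes the sample at
    which the peripheral target was illuminated.  ``reach_duration_ms`` is
    the time from illumination to first cursor entry into the target, or
    ``None`` if the target was never reached.
    """

    trial_index: int
    target: Optional["Direction"]
    t_ms: np.ndarray
    hand_xy: np.ndarray
    shoulder_deg: np.ndarray
    elbow_deg: np.ndarray
    target_onset_ms: Optional[int]
    left_center: bool
    reached_target: bool
    reach_duration_ms: Optional[int]
    recorded_arm: str = "left"
    center_xy: Tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.t_ms = np.asarray(self.t_ms)
        self.hand_xy = np.asarray(self.hand_xy, dtype=float)
        self.shoulder_deg = np.asarray(self.shoulder_deg, dtype=float)
        self.elbow_deg = np.asarray(self.elbow_deg, dtype=float)
        n = len(self.t_ms)
        if self.hand_xy.shape != (n, 2):
            raise ValueError("hand_xy must be an (n, 2) array matching t_ms")
        if len(self.shoulder_deg) != n or len(self.elbow_deg) != n:
            raise ValueError("joint-angle series must match t_ms in length")
        if n >= 2 and not np.all(np.diff(self.t_ms) == 1):
            raise ValueError("t_ms must increase in strict 1-ms steps")
        if self.recorded_arm not in ("left", "right"):
            raise ValueError("recorded_arm must be 'left' or 'right'")
        if self.reached_target and not self.left_center:
            raise ValueError("reached_target implies left_center")
        if self.reached_target and self.target is None:
            raise ValueError("reached_target implies a target was shown")

    @property
    def n_samples(self) -> int:
        return len(self.t_ms)

    @property
    def target_shown(self) -> bool:
        return self.target is not None


@dataclass
class ParticipantSession:
    """One participant x side x timepoint block of scheduled trials."""

    participant_id: str
    side: str  # "more_affected" | "less_affected"
    timepoint: str  # "admission" | "discharge"
    recorded_arm: str  # "left" | "right"
    fma_ue: int
    trials: List[TrialRecord] = field(default_factory=list)
    seed: Optional[List[int]] = None

    def __post_init__(self) -> None:
        if self.side not in ("more_affected", "less_affected"):
            raise ValueError("side must be 'more_affected' or 'less_affected'")
        if self.timepoint not in ("admission", "discharge"):
            raise ValueError("timepoint must be 'admission' or 'discharge'")
        if self.recorded_arm not in ("left", "right"):
            raise ValueError("recorded_arm must be 'left' or 'right'")

    @property
    def n_trials(self) -> int:
        return len(self.trials)
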