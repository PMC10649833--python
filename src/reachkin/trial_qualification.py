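"""Trial inclusion rules for the two analysis arms.

Quality arm (movement time / path length / velocity peaks): a trial is
included only when a peripheral target appeared, the cursor reached it, and
it did so within the 3,000-ms reach limit.

Quantity arm (AP/ML displacement): a trial is included when a target
appeared and the hand left the central target, even if the target was never
reached.  The quality-included set is therefore always a subset of the
quantity-included set.

Hold-failure trials (the trial counter advanced without a target) count in
the denominator of the exclusion percentages, matching a 64-trial counter
that increments regardless of target appearance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

from .records import ParticipantSession, TrialRecord
from .task_protocol import Direction, TaskConfig

__all__ = ["QualificationReport", "qualify_quality", "qualify_quantity"]


@dataclass(frozen=True)
class QualificationReport:
    """Tally of included/excluded trials for one session and analysis arm."""

    analysis_arm: str  # "quality" | "quantity"
    n_total: int
    n_excluded: int
    n_no_target: int
    n_failed_rule: int
    included_by_direction: Dict[Direction, int] = field(default_factory=dict)

    @property
    def n_included(self) -> int:
        return self.n_total - self.n_excluded

    @property
    def pct_excluded(self) -> float:
        if self.n_total == 0:
            return 0.0
        return 100.0 * self.n_excluded / self.n_total


def _report(
    arm: str, session: ParticipantSession, included: List[TrialRecord]
) -> QualificationReport:
    n_total = session.n_trials
    n_no_target = sum(1 for t in session.trials if not t.target_shown)
    counts: Dict[Direction, int] = {}
    for t in included:
        counts[t.target] = counts.get(t.target, 0) + 1
    n_excluded = n_total - len(included)
    return QualificationReport(
        analysis_arm=arm,
        n_total=n_total,
        n_excluded=n_excluded,
        n_no_target=n_no_target,
        n_failed_rule=n_excluded - n_no_target,
        included_by_direction=counts,
    )


def qualify_quality(
    session: ParticipantSession, config: TaskConfig = TaskConfig()
) -> Tuple[List[TrialRecord], QualificationReport]:
    """Quality-arm inclusion: target shown, reached, within the reach limit."""
    included = [
        t
        for t in session.trials
        if t.target_shown
        and t.reached_target
        and t.reach_duration_ms is not None
        and t.reach_duration_ms <= config.reach_limit
    ]
    return included, _report("quality", session, included)


def qualify_quantity(
    session: ParticipantSession, config: TaskConfig = TaskConfig()
) -> Tuple[List[TrialRecord], QualificationReport]:
    """Quantity-arm inclusion: target shown and the hand left the centre;
    reaching success is irrelevant."""
    included = [t for t in session.trials if t.target_shown and t.left_center]
    return included, _report("quantity", session, included)
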