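"""On-disk serialization of sessions: delimited sample tables + JSON headers.

One session is stored as a pair of files named
``<participant>_<side>_<timepoint>``:

* ``.csv`` -- long-format samples with columns ``trial, t_ms, x_cm, y_cm,
  shoulder_deg, elbow_deg``;
* ``.json`` -- the session header (participant, side, timepoint, recorded
  arm, clinical score, seed) plus per-trial event annotations (target,
  illumination time, outcome flags).

A cohort directory additionally holds ``manifest.csv`` listing every
session file with its group assignment.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Iterator, List, Optional, Tuple

import numpy as np
import pandas as pd

from .records import ParticipantSession, TrialRecord
from .task_protocol import Direction, classify_severity

__all__ = [
    "session_basename",
    "write_session",
    "read_session",
    "write_manifest",
    "read_cohort",
]


def session_basename(session: ParticipantSession) -> str:
    return f"{session.participant_id}_{session.side}_{session.timepoint}"


def write_session(session: ParticipantSession, out_dir: Path) -> Tuple[Path, Path]:
    """Write one session as a CSV sample table plus a JSON header."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    base = session_basename(session)
    csv_path = out_dir / f"{base}.csv"
    json_path = out_dir / f"{base}.json"

    frames = []
    events = []
    for trial in session.trials:
        frames.append(
            pd.DataFrame(
                {
                    "trial": trial.trial_index,
                    "t_ms": trial.t_ms,
                    "x_cm": trial.hand_xy[:, 0],
                    "y_cm": trial.hand_xy[:, 1],
                    "shoulder_deg": trial.shoulder_deg,
                    "elbow_deg": trial.elbow_deg,
                }
            )
        )
        events.append(
            {
                "trial": trial.trial_index,
                "target": trial.target.value if trial.target else None,
                "target_onset_ms": trial.target_onset_ms,
                "left_center": trial.left_center,
                "reached_target": trial.reached_target,
                "reach_duration_ms": trial.reach_duration_ms,
            }
        )
    samples = pd.concat(frames, ignore_index=True)
    samples.to_csv(
        csv_path,
        index=False,
        float_format="%.4f",
    )
    header = {
        "participant_id": session.participant_id,
        "side": session.side,
        "timepoint": session.timepoint,
        "recorded_arm": session.recorded_arm,
        "fma_ue": session.fma_ue,
        "seed": session.seed,
        "trials": events,
    }
    json_path.write_text(json.dumps(header, indent=1))
    return csv_path, json_path


def read_session(csv_path: Path, json_path: Optional[Path] = None) -> ParticipantSession:
    """Reconstruct a session from its CSV/JSON file pair."""
    csv_path = Path(csv_path)
    if json_path is None:
        json_path = csv_path.with_suffix(".json")
    header = json.loads(Path(json_path).read_text())
    samples = pd.read_csv(csv_path)
    events = {e["trial"]: e for e in header["trials"]}
    trials: List[TrialRecord] = []
    for trial_idx, grp in samples.groupby("trial", sort=True):
        ev = events[int(trial_idx)]
        trials.append(
            TrialRecord(
                trial_index=int(trial_idx),
                target=Direction(ev["target"]) if ev["target"] else None,
                t_ms=grp["t_ms"].to_numpy(),
                hand_xy=grp[["x_cm", "y_cm"]].to_numpy(),
                shoulder_deg=grp["shoulder_deg"].to_numpy(),
                elbow_deg=grp["elbow_deg"].to_numpy(),
                target_onset_ms=ev["target_onset_ms"],
                left_center=bool(ev["left_center"]),
                reached_target=bool(ev["reached_target"]),
                reach_duration_ms=ev["reach_duration_ms"],
                recorded_arm=header["recorded_arm"],
            )
        )
    return ParticipantSession(
        participant_id=header["participant_id"],
        side=header["side"],
        timepoint=header["timepoint"],
        recorded_arm=header["recorded_arm"],
        fma_ue=int(header["fma_ue"]),
        trials=trials,
        seed=header.get("seed"),
    )


def write_manifest(rows: Iterable[dict], out_dir: Path) -> Path:
    path = Path(out_dir) / "manifest.csv"
    pd.DataFrame(list(rows)).to_csv(path, index=False)
    return path


def read_cohort(cohort_dir: Path) -> Iterator[ParticipantSession]:
    """Yield every session listed in a cohort directory's manifest."""
    cohort_dir = Path(cohort_dir)
    manifest = pd.read_csv(cohort_dir / "manifest.csv")
    for _, row in manifest.iterrows():
        yield read_session(cohort_dir / row["csv_file"])
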