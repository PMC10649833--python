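"""End-to-end analysis: sessions -> per-trial metrics -> group statistics.

The analyze pass mirrors every right-arm session into the left-arm frame,
derives per-session speed thresholds, applies both qualification regimes,
extracts the per-trial metrics, and then runs the group analyses:

* mild group (clinical score > 45 at admission): per-direction cell means
  of movement time / path length / velocity peaks and the three-way
  repeated-measures ANOVA, plus spider-plot and normalized joint-path
  export tables;
* moderate-to-severe group: participant-pooled mediolateral proportion and
  the side x time random-intercept mixed model, plus hand-path 2-D
  histogram counts;
* both groups: paired t test on the clinical scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd

from .group_inference import (
    AnovaResult,
    LmmResult,
    PairedTResult,
    QUALITY_METRICS,
    aggregate,
    fit_lmm_proportion,
    paired_t,
    rm_anova_3way,
)
from .kinematic_metrics import (
    MetricOptions,
    compute_thresholds,
    compute_trial_metrics,
    displacement_components,
    resample_joint_angles,
    target_entry_index,
    _illumination_index,
)
from .records import ParticipantSession
from .task_protocol import (
    DIRECTION_ORDER,
    SeverityGroup,
    TaskConfig,
    classify_severity,
    mirror_to_left,
)
from .trial_qualification import qualify_quality, qualify_quantity

__all__ = ["AnalysisResult", "analyze_sessions", "session_trial_table"]

log = logging.getLogger(__name__)

HIST_EXTENT_CM = 14.0
HIST_BIN_CM = 0.25


@dataclass
class AnalysisResult:
    """Everything the analyze pass produces, as exportable tables."""

    trial_metrics: pd.DataFrame
    qualification: pd.DataFrame
    quality_cells: pd.DataFrame
    quantity_table: pd.DataFrame
    anova: Dict[str, AnovaResult]
    lmm: Optional[LmmResult]
    fma_tests: Dict[str, PairedTResult]
    spider: pd.DataFrame
    joint_paths: pd.DataFrame
    hand_histogram: pd.DataFrame

    def summary(self) -> str:
        lines = []
        n_part = self.trial_metrics["participant"].nunique()
        lines.append(f"participants analyzed: {n_part}")
        for arm in ("quality", "quantity"):
            sub = self.qualification[self.qualification["analysis_arm"] == arm]
            if len(sub):
                lines.append(
                    f"{arm} arm: mean excluded {sub['pct_excluded'].mean():.1f}%"
                )
        for metric, res in self.anova.items():
            direction = res.effect("direction")
            lines.append(
                f"ANOVA {metric}: direction F={direction['F']:.2f} "
                f"(df {direction['df1']:.1f}, {direction['df2']:.1f}), "
                f"P={direction['p']:.4g}"
            )
        if self.lmm is not None:
            inter = self.lmm.effect("side x timepoint")
            lines.append(
                f"LMM ml%: side x time F={inter['F']:.2f} "
                f"(df 1, {inter['df2']:.1f}), P={inter['p']:.4g}"
            )
        for group, res in self.fma_tests.items():
            lines.append(
                f"FMA-UE paired t ({group}): t({res.df})={res.t:.2f}, "
                f"P={res.p:.4g}"
            )
        return "\n".join(lines)


def session_trial_table(
    session: ParticipantSession,
    group: SeverityGroup,
    config: TaskConfig = TaskConfig(),
    options: MetricOptions = MetricOptions(),
) -> Tuple[pd.DataFrame, List[dict], List[dict]]:
    """Per-trial metric rows, qualification rows, and joint-path rows for
    one session (already expected in the left-arm frame)."""
    quality_trials, quality_rep = qualify_quality(session, config)
    quantity_trials, quantity_rep = qualify_quantity(session, config)
    quality_set = {t.trial_index for t in quality_trials}
    quantity_set = {t.trial_index for t in quantity_trials}

    thresholds = None
    if quality_trials:
        try:
            thresholds = compute_thresholds(session.trials, config, options)
        except ValueError as exc:  # no usable pre-illumination window
            log.warning(
                "%s: speed thresholds unavailable (%s); quality metrics skipped",
                session.participant_id,
                exc,
            )

    meta = {
        "participant": session.participant_id,
        "group": group.value,
        "side": session.side,
        "timepoint": session.timepoint,
        "recorded_arm": session.recorded_arm,
        "fma_ue": session.fma_ue,
    }
    rows = []
    joint_rows = []
    for trial in session.trials:
        row = dict(meta)
        row.update(
            {
                "trial": trial.trial_index,
                "direction": trial.target.value if trial.target else None,
                "target_shown": trial.target_shown,
                "left_center": trial.left_center,
                "reached_target": trial.reached_target,
                "reach_duration_ms": trial.reach_duration_ms,
                "quality_included": trial.trial_index in quality_set,
                "quantity_included": trial.trial_index in quantity_set,
                "movement_time_ms": np.nan,
                "path_length_cm": np.nan,
                "n_velocity_peaks": np.nan,
                "ap_total_cm": np.nan,
                "ml_total_cm": np.nan,
                "onset_ms": np.nan,
                "offset_ms": np.nan,
                "onset_fallback": False,
            }
        )
        if trial.trial_index in quality_set and thresholds is not None:
            m = compute_trial_metrics(trial, thresholds, config, options)
            row.update(
                {
                    "movement_time_ms": m.movement_time_ms,
                    "path_length_cm": m.path_length_cm,
                    "n_velocity_peaks": m.n_velocity_peaks,
                    "ap_total_cm": m.ap_total_cm,
                    "ml_total_cm": m.ml_total_cm,
                    "onset_ms": m.onset_ms,
                    "offset_ms": m.offset_ms,
                    "onset_fallback": m.onset_fallback,
                }
            )
            path = resample_joint_angles(trial, m.onset_ms, m.offset_ms)
            joint_rows.append(
                {
                    **meta,
                    "direction": trial.target.value,
                    "shoulder_delta": path.shoulder_delta,
                    "elbow_delta": path.elbow_delta,
                }
            )
        elif trial.trial_index in quantity_set:
            ap, ml = displacement_components(trial, config, options)
            row.update({"ap_total_cm": ap, "ml_total_cm": ml})
        rows.append(row)

    frame = pd.DataFrame(rows)
    float_cols = [
        "movement_time_ms",
        "path_length_cm",
        "n_velocity_peaks",
        "ap_total_cm",
        "ml_total_cm",
        "onset_ms",
        "offset_ms",
        "reach_duration_ms",
    ]
    frame[float_cols] = frame[float_cols].astype(float)
    frame["direction"] = frame["direction"].astype(object)

    qual_rows = []
    for rep in (quality_rep, quantity_rep):
        qual_rows.append(
            {
                **meta,
                "analysis_arm": rep.analysis_arm,
                "n_total": rep.n_total,
                "n_excluded": rep.n_excluded,
                "n_no_target": rep.n_no_target,
                "n_failed_rule": rep.n_failed_rule,
                "pct_excluded": rep.pct_excluded,
            }
        )
    return frame, qual_rows, joint_rows


def _hand_histogram(
    sessions_samples: List[Tuple[str, str, np.ndarray]]
) -> pd.DataFrame:
    """2-D histogram counts of hand samples per (side, timepoint), 0.25-cm
    bins over a +/-14-cm window around the start position."""
    edges = np.arange(-HIST_EXTENT_CM, HIST_EXTENT_CM + HIST_BIN_CM / 2, HIST_BIN_CM)
    out = []
    acc: Dict[Tuple[str, str], np.ndarray] = {}
    for side, timepoint, xy in sessions_samples:
        h, _, _ = np.histogram2d(xy[:, 0], xy[:, 1], bins=[edges, edges])
        key = (side, timepoint)
        acc[key] = acc.get(key, 0) + h.astype(np.int64)
    centers = (edges[:-1] + edges[1:]) / 2.0
    for (side, timepoint), h in acc.items():
        ii, jj = np.nonzero(h)
        out.append(
            pd.DataFrame(
                {
                    "side": side,
                    "timepoint": timepoint,
                    "x_cm": centers[ii],
                    "y_cm": centers[jj],
                    "count": h[ii, jj].astype(int),
                }
            )
        )
    if not out:
        return pd.DataFrame(columns=["side", "timepoint", "x_cm", "y_cm", "count"])
    return pd.concat(out, ignore_index=True)


def analyze_sessions(
    sessions: Iterable[ParticipantSession],
    config: TaskConfig = TaskConfig(),
    options: MetricOptions = MetricOptions(),
    alpha: float = 0.05,
) -> AnalysisResult:
    """Run the full group analysis over an iterable of sessions.

    Sessions are consumed lazily (one session's raw samples in memory at a
    time).  Group assignment uses the admission-timepoint clinical score.
    """
    trial_frames: List[pd.DataFrame] = []
    qual_rows: List[dict] = []
    joint_rows: List[dict] = []
    hist_samples: List[Tuple[str, str, np.ndarray]] = []
    fma_by_participant: Dict[str, Dict[str, int]] = {}
    admission_fma: Dict[str, int] = {}

    # First pass is streaming; group assignment needs the admission score,
    # which generated cohorts provide on every session of a participant.
    for session in sessions:
        session = ParticipantSession(
            participant_id=session.participant_id,
            side=session.side,
            timepoint=session.timepoint,
            recorded_arm=session.recorded_arm,
            fma_ue=session.fma_ue,
            trials=[mirror_to_left(t) for t in session.trials],
            seed=session.seed,
        )
        fma_by_participant.setdefault(session.participant_id, {})[
            session.timepoint
        ] = session.fma_ue
        if session.timepoint == "admission":
            admission_fma[session.participant_id] = session.fma_ue
        group = classify_severity(
            admission_fma.get(session.participant_id, session.fma_ue)
        ).group
        trials_df, q_rows, j_rows = session_trial_table(
            session, group, config, options
        )
        trial_frames.append(trials_df)
        qual_rows.extend(q_rows)
        joint_rows.extend(j_rows)
        if group is SeverityGroup.MODERATE_TO_SEVERE:
            for trial in session.trials:
                if trial.target_shown and trial.left_center:
                    i0 = _illumination_index(trial)
                    entry = target_entry_index(trial, config, options)
                    i1 = entry if entry is not None else min(
                        trial.n_samples - 1, i0 + config.reach_limit
                    )
                    hist_samples.append(
                        (session.side, session.timepoint, trial.hand_xy[i0 : i1 + 1])
                    )

    metrics = pd.concat(trial_frames, ignore_index=True)
    qualification = pd.DataFrame(qual_rows)

    # Quality arm: mild group only (the group able to reach all directions).
    mild_rows = metrics[metrics["group"] == SeverityGroup.MILD.value]
    quality_cells = aggregate(mild_rows, "quality") if len(mild_rows) else pd.DataFrame()
    anova: Dict[str, AnovaResult] = {}
    if len(quality_cells):
        for metric in QUALITY_METRICS:
            try:
                anova[metric] = rm_anova_3way(
                    quality_cells,
                    metric,
                    alpha=alpha,
                    level_orders={
                        "direction": [d.value for d in DIRECTION_ORDER],
                        "side": ["more_affected", "less_affected"],
                        "timepoint": ["admission", "discharge"],
                    },
                )
            except ValueError as exc:
                log.warning("ANOVA for %s skipped: %s", metric, exc)

    # Quantity arm: moderate-to-severe group, both sides.
    severe_rows = metrics[
        metrics["group"] == SeverityGroup.MODERATE_TO_SEVERE.value
    ]
    quantity_table = (
        aggregate(severe_rows, "quantity") if len(severe_rows) else pd.DataFrame()
    )
    lmm: Optional[LmmResult] = None
    if len(quantity_table) and quantity_table["ml_pct"].notna().sum() >= 4:
        try:
            lmm = fit_lmm_proportion(quantity_table, alpha=alpha)
        except ValueError as exc:
            log.warning("mixed model skipped: %s", exc)

    # Clinical-score paired t per group.
    groups = metrics[["participant", "group"]].drop_duplicates().set_index(
        "participant"
    )["group"]
    fma_tests: Dict[str, PairedTResult] = {}
    for group_name in (SeverityGroup.MILD.value, SeverityGroup.MODERATE_TO_SEVERE.value):
        pids = [p for p in groups.index if groups[p] == group_name]
        pairs = [
            (fma_by_participant[p]["admission"], fma_by_participant[p]["discharge"])
            for p in pids
            if {"admission", "discharge"} <= set(fma_by_participant[p])
        ]
        if len(pairs) >= 2:
            adm, dis = zip(*pairs)
            try:
                fma_tests[group_name] = paired_t(adm, dis)
            except ValueError as exc:
                log.warning("paired t for %s skipped: %s", group_name, exc)

    # Spider-plot table: direction x side x time group means +/- SEM.
    if len(quality_cells):
        spider = (
            quality_cells.groupby(["direction", "side", "timepoint"], observed=True)[
                list(QUALITY_METRICS)
            ]
            .agg(["mean", "sem"])
            .reset_index()
        )
        spider.columns = [
            "_".join(c).rstrip("_") if isinstance(c, tuple) else c
            for c in spider.columns
        ]
    else:
        spider = pd.DataFrame()

    # Normalized joint-path table: mean delta-angle trajectory per
    # participant x side x time x direction, long format over the grid.
    if joint_rows:
        jp = pd.DataFrame(joint_rows)
        collapsed = (
            jp.groupby(
                ["participant", "side", "timepoint", "direction"], observed=True
            )
            .agg(
                shoulder_delta=("shoulder_delta", lambda s: np.mean(np.stack(s), axis=0)),
                elbow_delta=("elbow_delta", lambda s: np.mean(np.stack(s), axis=0)),
            )
            .reset_index()
        )
        grid = np.linspace(0.0, 100.0, 101)
        long_rows = []
        for _, r in collapsed.iterrows():
            long_rows.append(
                pd.DataFrame(
                    {
                        "participant": r["participant"],
                        "side": r["side"],
                        "timepoint": r["timepoint"],
                        "direction": r["direction"],
                        "percent": grid,
                        "shoulder_delta_deg": r["shoulder_delta"],
                        "elbow_delta_deg": r["elbow_delta"],
                    }
                )
            )
        joint_paths = pd.concat(long_rows, ignore_index=True)
    else:
        joint_paths = pd.DataFrame()

    return AnalysisResult(
        trial_metrics=metrics,
        qualification=qualification,
        quality_cells=quality_cells,
        quantity_table=quantity_table,
        anova=anova,
        lmm=lmm,
        fma_tests=fma_tests,
        spider=spider,
        joint_paths=joint_paths,
        hand_histogram=_hand_histogram(hist_samples),
    )
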