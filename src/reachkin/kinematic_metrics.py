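"""Per-trial movement parameters of center-out reaching.

Quality metrics (for participants able to complete reaches):

* movement time -- elapsed time from movement onset to offset;
* path length  -- hand distance traveled between onset and offset;
* velocity peaks -- count of local maxima of the low-pass-filtered hand
  speed between onset and offset, a movement-smoothness proxy.

Movement onset uses a dual-threshold backward search: per session, a lower
threshold (median) and an upper threshold (95th percentile) are taken from
the pooled hand speed in the 500 ms preceding every target illumination.
The first post-illumination sample at which the cursor leaves the central
target anchors a backward scan; the onset is the latest sample at or before
that anchor which is either a strict local speed minimum below the upper
threshold or a sample with speed below the lower threshold, falling back to
the illumination time if the scan exhausts.  Movement offset is the first
cursor entry into the peripheral target.

Quantity metrics (for participants who often cannot complete reaches):
anteroposterior and mediolateral total displacement, the per-axis sums of
unsigned per-millisecond steps, AP_total = sum |y[t+1]-y[t]| and
ML_total = sum |x[t+1]-x[t]|, plus the participant-pooled mediolateral
proportion 100*ML/(AP+ML).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import signal

from .records import TrialRecord
from .task_protocol import Direction, TaskConfig, direction_unit_vector

__all__ = [
    "SpeedThresholds",
    "TrialMetrics",
    "NormalizedJointPath",
    "MetricOptions",
    "compute_speed",
    "compute_thresholds",
    "detect_onset",
    "detect_offset",
    "path_length",
    "filter_speed",
    "count_velocity_peaks",
    "displacement_components",
    "participant_ml_proportion",
    "resample_joint_angles",
    "compute_trial_metrics",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SpeedThresholds:
    """Lower (median) and upper (95th-percentile) pre-illumination speed
    thresholds, in cm/s."""

    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not 0 <= self.lower <= self.upper:
            raise ValueError("thresholds must satisfy 0 <= lower <= upper")


@dataclass(frozen=True)
class TrialMetrics:
    """Derived quantities of a single qualified trial."""

    onset_ms: int
    offset_ms: int
    movement_time_ms: int
    path_length_cm: float
    n_velocity_peaks: int
    ap_total_cm: float
    ml_total_cm: float
    onset_fallback: bool = False


@dataclass(frozen=True)
class NormalizedJointPath:
    """Shoulder/elbow delta angles resampled onto a 0-100% movement grid."""

    percent: np.ndarray
    shoulder_delta: np.ndarray
    elbow_delta: np.ndarray


@dataclass(frozen=True)
class MetricOptions:
    """Analysis choices left open by the protocol description.

    * ``percentile_method``: "pooled" pools every pre-illumination speed
      sample across trials before taking the median/95th percentile;
      "per_trial" takes the median of per-trial statistics instead.
    * ``entry_rule``: "center" counts the cursor as inside a target when the
      cursor centre is within the target circle; "overlap" when the two
      circles merely intersect.
    * ``displacement_span``: "outbound" sums AP/ML steps from illumination to
      the end of the outbound reach phase (target entry, the reach time
      limit, or the end of the recording); "full" uses the whole
      post-illumination recording.
    """

    percentile_method: str = "pooled"
    entry_rule: str = "center"
    displacement_span: str = "outbound"
    threshold_window_ms: int = 500
    filter_cutoff_hz: float = 10.0
    filter_order: int = 6

    def __post_init__(self) -> None:
        if self.percentile_method not in ("pooled", "per_trial"):
            raise ValueError("percentile_method must be 'pooled' or 'per_trial'")
        if self.entry_rule not in ("center", "overlap"):
            raise ValueError("entry_rule must be 'center' or 'overlap'")
        if self.displacement_span not in ("outbound", "full"):
            raise ValueError("displacement_span must be 'outbound' or 'full'")
        if self.threshold_window_ms <= 0:
            raise ValueError("threshold_window_ms must be positive")

    def entry_radius(self, config: TaskConfig) -> float:
        if self.entry_rule == "center":
            return config.peripheral_radius
        return config.peripheral_radius + config.cursor_radius


def compute_speed(hand_xy: np.ndarray, rate: float) -> np.ndarray:
    """Hand speed (cm/s) by central differences, one-sided at the ends."""
    hand_xy = np.asarray(hand_xy, dtype=float)
    if hand_xy.ndim != 2 or hand_xy.shape[1] != 2:
        raise ValueError("hand_xy must be an (n, 2) array")
    if hand_xy.shape[0] < 3:
        raise ValueError("need at least 3 samples to differentiate")
    dt = 1.0 / rate
    vel = np.gradient(hand_xy, dt, axis=0)
    return np.hypot(vel[:, 0], vel[:, 1])


def _pre_illumination_windows(
    trials: Iterable[TrialRecord], config: TaskConfig, window_ms: int
) -> List[np.ndarray]:
    windows = []
    for trial in trials:
        if trial.target_onset_ms is None:
            continue
        i0 = int(trial.target_onset_ms)
        if i0 < window_ms or trial.n_samples < 3:
            continue
        speed = compute_speed(trial.hand_xy, config.sample_rate)
        windows.append(speed[i0 - window_ms : i0])
    return windows


def compute_thresholds(
    trials: Sequence[TrialRecord],
    config: TaskConfig,
    options: MetricOptions = MetricOptions(),
) -> SpeedThresholds:
    """Session-level speed thresholds from the 500 ms before illumination.

    All per-millisecond speed samples from the pre-illumination windows of
    every shown-target trial are pooled; the lower threshold is the pooled
    median and the upper threshold the pooled 95th percentile (linear
    interpolation between closest ranks).
    """
    windows = _pre_illumination_windows(trials, config, options.threshold_window_ms)
    if not windows:
        raise ValueError(
            "no trial provides a full pre-illumination window; "
            "cannot form speed thresholds"
        )
    if options.percentile_method == "pooled":
        pool = np.concatenate(windows)
        lower = float(np.median(pool))
        upper = float(np.percentile(pool, 95))
    else:
        lower = float(np.median([np.median(w) for w in windows]))
        upper = float(np.median([np.percentile(w, 95) for w in windows]))
    # Guard against pathological pools where rounding makes upper < lower.
    upper = max(upper, lower)
    return SpeedThresholds(lower=lower, upper=upper)


def _illumination_index(trial: TrialRecord) -> int:
    if trial.target_onset_ms is None:
        raise ValueError(
            f"trial {trial.trial_index}: no target was shown; "
            "onset/offset are undefined"
        )
    i0 = int(np.searchsorted(trial.t_ms, trial.target_onset_ms))
    if i0 >= trial.n_samples or trial.t_ms[i0] != trial.target_onset_ms:
        raise ValueError(
            f"trial {trial.trial_index}: target_onset_ms not on the time grid"
        )
    return i0


def _center_distance(trial: TrialRecord) -> np.ndarray:
    c = np.asarray(trial.center_xy, dtype=float)
    return np.hypot(trial.hand_xy[:, 0] - c[0], trial.hand_xy[:, 1] - c[1])


def leave_center_index(trial: TrialRecord, config: TaskConfig) -> Optional[int]:
    """First post-illumination sample at which the cursor left the centre,
    or ``None`` if it never did."""
    i0 = _illumination_index(trial)
    outside = _center_distance(trial)[i0:] > config.exit_radius
    hits = np.nonzero(outside)[0]
    if hits.size == 0:
        return None
    return i0 + int(hits[0])


def detect_onset(
    trial: TrialRecord,
    thresholds: SpeedThresholds,
    config: TaskConfig,
) -> Tuple[int, bool]:
    """Movement onset (ms) by the dual-threshold backward search.

    Returns ``(onset_ms, fallback)`` where ``fallback`` is True when the
    backward scan reached the illumination time without meeting either
    criterion and the illumination time itself was returned.
    """
    i0 = _illumination_index(trial)
    i_leave = leave_center_index(trial, config)
    if i_leave is None:
        raise ValueError(
            f"trial {trial.trial_index}: hand never left the central target; "
            "movement onset is undefined"
        )
    speed = compute_speed(trial.hand_xy, config.sample_rate)
    n = speed.size
    local_min = np.zeros(n, dtype=bool)
    local_min[1:-1] = (speed[1:-1] < speed[:-2]) & (speed[1:-1] < speed[2:])
    candidate = (speed < thresholds.lower) | (
        local_min & (speed < thresholds.upper)
    )
    idx = np.nonzero(candidate[i0 : i_leave + 1])[0]
    if idx.size == 0:
        return int(trial.t_ms[i0]), True
    return int(trial.t_ms[i0 + idx[-1]]), False


def _target_center(trial: TrialRecord, config: TaskConfig) -> np.ndarray:
    if trial.target is None:
        raise ValueError(f"trial {trial.trial_index}: no target was shown")
    return (
        np.asarray(trial.center_xy, dtype=float)
        + config.target_distance * direction_unit_vector(trial.target)
    )


def target_entry_index(
    trial: TrialRecord,
    config: TaskConfig,
    options: MetricOptions = MetricOptions(),
) -> Optional[int]:
    """First post-illumination sample with the cursor inside the target."""
    i0 = _illumination_index(trial)
    tgt = _target_center(trial, config)
    dist = np.hypot(
        trial.hand_xy[i0:, 0] - tgt[0], trial.hand_xy[i0:, 1] - tgt[1]
    )
    hits = np.nonzero(dist <= options.entry_radius(config))[0]
    if hits.size == 0:
        return None
    return i0 + int(hits[0])


def detect_offset(
    trial: TrialRecord,
    config: TaskConfig,
    options: MetricOptions = MetricOptions(),
) -> int:
    """Movement offset (ms): first cursor entry into the peripheral target."""
    entry = target_entry_index(trial, config, options)
    if entry is None:
        raise ValueError(
            f"trial {trial.trial_index}: cursor never entered the target; "
            "this trial should have been excluded from the quality analysis"
        )
    return int(trial.t_ms[entry])


def path_length(trial: TrialRecord, onset_ms: int, offset_ms: int) -> float:
    """Hand distance traveled (cm) between onset and offset, inclusive."""
    if onset_ms > offset_ms:
        raise ValueError("onset must not be later than offset")
    i_on = int(np.searchsorted(trial.t_ms, onset_ms))
    i_off = int(np.searchsorted(trial.t_ms, offset_ms))
    seg = trial.hand_xy[i_on : i_off + 1]
    if seg.shape[0] < 2:
        return 0.0
    steps = np.diff(seg, axis=0)
    return float(np.hypot(steps[:, 0], steps[:, 1]).sum())


def filter_speed(
    speed: np.ndarray,
    rate: float,
    cutoff: float = 10.0,
    order: int = 6,
) -> np.ndarray:
    """Zero-phase low-pass Butterworth filter of a speed series.

    An order-6 design applied forward and backward (double pass), so the
    magnitude response is the squared Butterworth response and the phase is
    exactly zero.  Constant series pass through unchanged (unit DC gain).
    """
    speed = np.asarray(speed, dtype=float)
    if speed.ndim != 1:
        raise ValueError("speed must be a 1-D series")
    sos = signal.butter(order, cutoff, btype="low", fs=rate, output="sos")
    padlen = 3 * (2 * sos.shape[0] + 1)
    if speed.size <= padlen:
        raise ValueError(
            f"series of {speed.size} samples is shorter than the filter "
            f"warm-up ({padlen + 1} samples minimum)"
        )
    return signal.sosfiltfilt(sos, speed, padlen=padlen)


def count_velocity_peaks(
    filtered_speed: np.ndarray,
    t_ms: np.ndarray,
    onset_ms: int,
    offset_ms: int,
) -> int:
    """Count strict local maxima of the filtered speed in [onset, offset].

    A peak is an interior sample strictly greater than both neighbours; no
    amplitude or spacing thresholds are applied, and plateau samples or the
    window endpoints are never peaks.
    """
    if onset_ms >= offset_ms:
        raise ValueError("onset must precede offset")
    i_on = int(np.searchsorted(t_ms, onset_ms))
    i_off = int(np.searchsorted(t_ms, offset_ms))
    seg = np.asarray(filtered_speed, dtype=float)[i_on : i_off + 1]
    if seg.size < 3:
        return 0
    interior = (seg[1:-1] > seg[:-2]) & (seg[1:-1] > seg[2:])
    return int(np.count_nonzero(interior))


def _reach_phase_end(
    trial: TrialRecord, config: TaskConfig, options: MetricOptions
) -> int:
    """Last sample index of the outbound reach phase."""
    i0 = _illumination_index(trial)
    end = trial.n_samples - 1
    if options.displacement_span == "full":
        return end
    entry = target_entry_index(trial, config, options)
    if entry is not None:
        return entry
    return min(end, i0 + config.reach_limit)


def displacement_components(
    trial: TrialRecord,
    config: TaskConfig,
    options: MetricOptions = MetricOptions(),
) -> Tuple[float, float]:
    """(AP_total, ML_total): per-axis sums of unsigned per-sample steps.

    Computed from target illumination to the end of the outbound reach
    phase.  Requires that a target appeared and that the hand left the
    central target.
    """
    i0 = _illumination_index(trial)
    if leave_center_index(trial, config) is None:
        raise ValueError(
            f"trial {trial.trial_index}: hand never left the central target; "
            "displacement components are not defined for this trial"
        )
    i1 = _reach_phase_end(trial, config, options)
    seg = trial.hand_xy[i0 : i1 + 1]
    steps = np.abs(np.diff(seg, axis=0))
    ml_total = float(steps[:, 0].sum())
    ap_total = float(steps[:, 1].sum())
    return ap_total, ml_total


def participant_ml_proportion(
    trials: Sequence[TrialRecord],
    config: TaskConfig,
    options: MetricOptions = MetricOptions(),
) -> Optional[float]:
    """Pooled mediolateral proportion, 100*ML/(AP+ML), over qualified trials.

    Returns ``None`` (a missing observation) when the pooled total is zero
    or no trial qualifies, mirroring participants unable to produce any
    scoreable movement.
    """
    ap_sum = 0.0
    ml_sum = 0.0
    any_trial = False
    for trial in trials:
        ap, ml = displacement_components(trial, config, options)
        ap_sum += ap
        ml_sum += ml
        any_trial = True
    if not any_trial or ap_sum + ml_sum == 0.0:
        return None
    return 100.0 * ml_sum / (ap_sum + ml_sum)


def resample_joint_angles(
    trial: TrialRecord,
    onset_ms: int,
    offset_ms: int,
    grid_size: int = 101,
) -> NormalizedJointPath:
    """Delta joint angles resampled onto a 0-100% movement-time grid.

    Angles are expressed relative to the onset posture, so the first grid
    point is exactly (0, 0); the grid length is fixed regardless of trial
    duration.
    """
    if onset_ms >= offset_ms:
        raise ValueError("onset must precede offset")
    i_on = int(np.searchsorted(trial.t_ms, onset_ms))
    i_off = int(np.searchsorted(trial.t_ms, offset_ms))
    sh = trial.shoulder_deg[i_on : i_off + 1]
    el = trial.elbow_deg[i_on : i_off + 1]
    pct = np.linspace(0.0, 100.0, grid_size)
    src = np.linspace(0.0, 100.0, sh.size)
    sh_d = np.interp(pct, src, sh - sh[0])
    el_d = np.interp(pct, src, el - el[0])
    sh_d[0] = 0.0
    el_d[0] = 0.0
    return NormalizedJointPath(percent=pct, shoulder_delta=sh_d, elbow_delta=el_d)


def compute_trial_metrics(
    trial: TrialRecord,
    thresholds: SpeedThresholds,
    config: TaskConfig,
    options: MetricOptions = MetricOptions(),
) -> TrialMetrics:
    """All per-trial metrics of a quality-qualified (completed) trial."""
    onset_ms, fallback = detect_onset(trial, thresholds, config)
    offset_ms = detect_offset(trial, config, options)
    speed = compute_speed(trial.hand_xy, config.sample_rate)
    filtered = filter_speed(
        speed, config.sample_rate, options.filter_cutoff_hz, options.filter_order
    )
    n_peaks = count_velocity_peaks(filtered, trial.t_ms, onset_ms, offset_ms)
    ap, ml = displacement_components(trial, config, options)
    return TrialMetrics(
        onset_ms=onset_ms,
        offset_ms=offset_ms,
        movement_time_ms=offset_ms - onset_ms,
        path_length_cm=path_length(trial, onset_ms, offset_ms),
        n_velocity_peaks=n_peaks,
        ap_total_cm=ap,
        ml_total_cm=ml,
        onset_fallback=fallback,
    )
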