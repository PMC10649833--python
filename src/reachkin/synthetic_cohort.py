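"""Seeded synthetic cohorts of center-out reaching sessions.

The study's raw recordings are not deposited, so every downstream stage is
exercised on synthetic sessions that carry the statistical structure the
analysis assumes:

* the trial state machine of the protocol (randomized 1,250-1,750-ms hold,
  hold failures without target appearance, 3,000-ms reach limit, blocked-
  random schedules in which every 8 consecutive scheduled targets cover all
  8 directions);
* smooth minimum-jerk reaches with optional corrective submovements, each
  adding exactly one velocity peak;
* direction-dependent impairment (slower, less smooth movement along the
  anteroposterior axis), side differences, and severity-dependent
  incomplete reaches whose mediolateral/anteroposterior energy split is a
  generator parameter (``ml_bias``);
* two-link-arm joint angles by planar inverse kinematics, anchored to the
  protocol's start posture (30 deg shoulder horizontal adduction, 90 deg
  elbow flexion) at the central target;
* 1-kHz sampling with positions quantized to 0.01 cm.

Reproducibility: one cohort seed expands to per-session seeds through a
documented counter scheme, ``SeedSequence((seed, 1, participant_index,
side_index, time_index))``, so any single session can be regenerated in
isolation; the cohort roster uses ``SeedSequence((seed, 0))``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterator, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import signal

from .records import ParticipantSession, TrialRecord
from .task_protocol import (
    DIRECTION_ORDER,
    Direction,
    SeverityGroup,
    TaskConfig,
    classify_severity,
    direction_unit_vector,
)

__all__ = [
    "ArmGeometry",
    "ImpairmentProfile",
    "CohortSpec",
    "Participant",
    "minimum_jerk_reach",
    "add_submovements",
    "simulate_trial",
    "simulate_session",
    "simulate_cohort",
    "cohort_participants",
    "iter_cohort_sessions",
    "joint_angles_from_hand",
    "hand_from_joint_angles",
    "impairment_profile",
]

RngLike = Union[int, np.random.SeedSequence, np.random.Generator, None]


def _rng(seed: RngLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Two-link arm geometry


@dataclass(frozen=True)
class ArmGeometry:
    """Planar two-link arm (upper arm + forearm/hand), elbow-down branch.

    Link lengths are adult-scale defaults; only the joint-angle outputs
    depend on them, never the hand-space metrics.  Shoulder horizontal
    adduction is positive toward the midline/forward; elbow flexion is
    positive with 0 deg meaning full extension.  The shoulder position is
    placed so the hand at the central target corresponds to the protocol's
    start posture.
    """

    upper_cm: float = 30.0
    forearm_cm: float = 33.0
    start_shoulder_deg: float = 30.0
    start_elbow_deg: float = 90.0

    def shoulder_offset(self) -> np.ndarray:
        """Shoulder position relative to the central target."""
        e1, e2 = _segment_units(self.start_shoulder_deg, self.start_elbow_deg)
        return -(self.upper_cm * e1 + self.forearm_cm * e2)


def _segment_units(shoulder_deg: float, elbow_deg: float):
    gamma = math.radians(180.0 - shoulder_deg)
    e1 = np.array([math.cos(gamma), math.sin(gamma)])
    phi2 = gamma - math.radians(elbow_deg)
    e2 = np.array([math.cos(phi2), math.sin(phi2)])
    return e1, e2


def hand_from_joint_angles(
    shoulder_deg: np.ndarray,
    elbow_deg: np.ndarray,
    geometry: ArmGeometry = ArmGeometry(),
    center: Sequence[float] = (0.0, 0.0),
) -> np.ndarray:
    """Forward kinematics: hand positions from joint-angle series."""
    shoulder_deg = np.asarray(shoulder_deg, dtype=float)
    elbow_deg = np.asarray(elbow_deg, dtype=float)
    gamma = np.radians(180.0 - shoulder_deg)
    phi2 = gamma - np.radians(elbow_deg)
    s = np.asarray(center, dtype=float) + geometry.shoulder_offset()
    x = s[0] + geometry.upper_cm * np.cos(gamma) + geometry.forearm_cm * np.cos(phi2)
    y = s[1] + geometry.upper_cm * np.sin(gamma) + geometry.forearm_cm * np.sin(phi2)
    return np.column_stack([x, y])


def joint_angles_from_hand(
    hand_xy: np.ndarray,
    geometry: ArmGeometry = ArmGeometry(),
    center: Sequence[float] = (0.0, 0.0),
    trial_index: Optional[int] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Inverse kinematics (elbow-down branch): (shoulder, elbow) deg series.

    Raises when a point falls outside the annulus the two-link arm can
    reach, naming the trial and sample.
    """
    hand_xy = np.atleast_2d(np.asarray(hand_xy, dtype=float))
    l1, l2 = geometry.upper_cm, geometry.forearm_cm
    s = np.asarray(center, dtype=float) + geometry.shoulder_offset()
    d = hand_xy - s
    r2 = d[:, 0] ** 2 + d[:, 1] ** 2
    cos_e = (r2 - l1 * l1 - l2 * l2) / (2.0 * l1 * l2)
    bad = (cos_e < -1.0 - 1e-9) | (cos_e > 1.0 + 1e-9)
    if np.any(bad):
        i = int(np.nonzero(bad)[0][0])
        label = f"trial {trial_index}, " if trial_index is not None else ""
        raise ValueError(
            f"{label}sample {i}: hand point {tuple(hand_xy[i])} is outside "
            f"the reachable annulus of the {l1}+{l2} cm arm"
        )
    elbow = np.degrees(np.arccos(np.clip(cos_e, -1.0, 1.0)))
    elbow_rad = np.radians(elbow)
    beta = np.degrees(np.arctan2(l2 * np.sin(elbow_rad), l1 + l2 * np.cos(elbow_rad)))
    phi = np.degrees(np.arctan2(d[:, 1], d[:, 0]))
    shoulder = 180.0 - (phi + beta)
    shoulder = (shoulder + 180.0) % 360.0 - 180.0
    return shoulder, elbow


# ---------------------------------------------------------------------------
# Reach primitives


def minimum_jerk_reach(
    start: Sequence[float],
    end: Sequence[float],
    duration_ms: float,
    rate: float = 1000.0,
) -> np.ndarray:
    """Minimum-jerk point-to-point path sampled at ``rate``, endpoints
    inclusive (a D-ms reach at 1 kHz has D+1 samples).

    The speed profile is the classic symmetric single-peaked bell.
    """
    if duration_ms <= 0:
        raise ValueError("duration must be positive")
    start = np.asarray(start, dtype=float)
    end = np.asarray(end, dtype=float)
    n = int(round(duration_ms * rate / 1000.0)) + 1
    tau = np.linspace(0.0, 1.0, n)
    s = 10.0 * tau**3 - 15.0 * tau**4 + 6.0 * tau**5
    return start[None, :] + np.outer(s, end - start)


def add_submovements(
    path: np.ndarray,
    k: int,
    amplitude: float = 0.8,
    seed: RngLike = None,
    rate: float = 1000.0,
    step_ms: Tuple[int, int] = (220, 300),
    lateral: float = 0.0,
) -> np.ndarray:
    """Append ``k`` corrective submovements to a reach path.

    The main path is shrunk (by a similarity transform of its displacement)
    so that it stops ``k * amplitude`` short of the original endpoint along
    the final approach direction; ``k`` discrete minimum-jerk steps then
    close the gap through waypoints spaced ``amplitude`` apart along the
    approach axis.  ``lateral`` > 0 swings the waypoints alternately to
    either side of the axis (``lateral * amplitude`` scale), producing the
    zigzag overshoot of corrective reaching and lengthening the hand path;
    ``lateral = 0`` keeps the corrections colinear.  Endpoints are
    unchanged.  Speed returns to zero between consecutive steps for a
    single sample only (a longer stationary pause would let the zero-phase
    Butterworth filter ring and create spurious peaks), so each step
    contributes exactly one additional local maximum to the filtered speed
    profile and the downstream peak count is ``1 + k`` for the default
    amplitude/spacing.
    """
    path = np.asarray(path, dtype=float)
    if k < 0:
        raise ValueError("k must be nonnegative")
    if k == 0:
        return path.copy()
    rng = _rng(seed)
    a = path[0]
    e = path[-1]
    tail = e - path[max(0, path.shape[0] - 50)]
    if np.hypot(*tail) < 1e-9:
        tail = e - a
    if np.hypot(*tail) < 1e-9:
        tail = np.array([1.0, 0.0])
    u = tail / np.hypot(*tail)
    v = np.array([-u[1], u[0]])
    sign = 1.0 if rng.random() < 0.5 else -1.0
    waypoints = []
    for i in range(k):
        ell = lateral * amplitude * rng.uniform(0.6, 1.0) * sign
        sign = -sign
        waypoints.append(e - (k - i) * amplitude * u + ell * v)
    waypoints.append(e.copy())
    e0 = waypoints[0]
    d_old = e - a
    d_new = e0 - a
    if np.hypot(*d_old) < 1e-12:
        main = np.tile(a, (path.shape[0], 1))
    else:
        z_old = complex(d_old[0], d_old[1])
        z_new = complex(d_new[0], d_new[1])
        z = z_new / z_old
        m = np.array([[z.real, -z.imag], [z.imag, z.real]])
        main = a[None, :] + (path - a[None, :]) @ m.T
    segments = [main]
    for start, stop in zip(waypoints[:-1], waypoints[1:]):
        dur = int(rng.integers(step_ms[0], step_ms[1] + 1))
        step = minimum_jerk_reach(start, stop, dur, rate)
        segments.append(step[1:])
    return np.vstack(segments)


def _smooth_noise(
    n: int, sd: float, rate: float, rng: np.random.Generator, cutoff: float = 5.0
) -> np.ndarray:
    """Low-pass-filtered white positional noise, per-axis SD ``sd`` cm.

    Models the slow baseline wander of a supported hand, so the
    pre-illumination speed thresholds are nonzero and nondegenerate.
    """
    if sd <= 0 or n < 40:
        return np.zeros((n, 2))
    white = rng.standard_normal((n, 2))
    sos = signal.butter(2, cutoff, btype="low", fs=rate, output="sos")
    smooth = signal.sosfiltfilt(sos, white, axis=0)
    std = smooth.std(axis=0)
    std[std == 0] = 1.0
    return smooth / std * sd


# ---------------------------------------------------------------------------
# Impairment profiles


@dataclass(frozen=True)
class ImpairmentProfile:
    """Knobs mapping impairment phenomenology onto trial generation.

    ``completion_prob_by_direction`` - chance a shown-target trial is
    completed; ``time_scale_by_direction`` - movement-duration multipliers
    (>= 1; anteroposterior directions scaled up); ``extra_submovements`` -
    Poisson rate of corrective submovements (scaled per direction by the
    time-scale, coupling slowness, path lengthening, and unsmoothness);
    ``ml_bias`` - share of excursion energy directed mediolaterally for
    incomplete movers; ``hold_failure_prob`` - chance the hold is broken and
    no target appears; ``move_prob`` - chance a shown-target trial produces
    any movement out of the centre; ``noise_sd`` - positional jitter SD (cm).
    """

    completion_prob_by_direction: Dict[Direction, float]
    time_scale_by_direction: Dict[Direction, float]
    extra_submovements: float = 0.0
    ml_bias: float = 0.5
    hold_failure_prob: float = 0.0
    noise_sd: float = 0.03
    move_prob: float = 1.0

    def __post_init__(self) -> None:
        for d in DIRECTION_ORDER:
            p = self.completion_prob_by_direction[d]
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"completion probability for {d} not in [0,1]")
            if self.time_scale_by_direction[d] < 1.0:
                raise ValueError(f"time scale for {d} must be >= 1")
        for name in ("ml_bias", "hold_failure_prob", "move_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0,1]")
        if self.extra_submovements < 0:
            raise ValueError("extra_submovements must be nonnegative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")

    @classmethod
    def from_scalars(
        cls,
        completion_prob: float = 1.0,
        time_scale: float = 1.0,
        ap_gain: float = 0.0,
        **kwargs,
    ) -> "ImpairmentProfile":
        """Build direction maps from a base value plus an anteroposterior
        gain: directions at angle theta get time scale
        ``time_scale * (1 + ap_gain * |sin theta|)``."""
        comp = {}
        scale = {}
        for d in DIRECTION_ORDER:
            apness = abs(math.sin(math.radians(d.angle_deg)))
            comp[d] = completion_prob
            scale[d] = time_scale * (1.0 + ap_gain * apness)
        return cls(
            completion_prob_by_direction=comp,
            time_scale_by_direction=scale,
            **kwargs,
        )


def impairment_profile(
    fma_ue: int,
    side: str,
    timepoint: str,
    ml_bias: float = 0.5,
) -> ImpairmentProfile:
    """Default severity -> kinematics mapping used by the cohort generator.

    The mapping is monotone in the clinical score and strictly no worse at
    discharge than at admission for a non-decreasing score: mild-range arms
    complete essentially all reaches but are slower, longer-pathed, and less
    smooth along the anteroposterior axis (more so on the more-affected
    side); low-score arms rarely complete reaches and instead produce
    mediolaterally biased sub-excursions, with very low scores sometimes
    failing to move at all.
    """
    level = classify_severity(fma_ue).level.value
    if side == "less_affected":
        return ImpairmentProfile.from_scalars(
            completion_prob=0.96,
            time_scale=1.04,
            ap_gain=0.30,
            extra_submovements=0.30,
            ml_bias=0.5,
            hold_failure_prob=0.03,
            noise_sd=0.03,
        )
    if level == "mild":
        # Impairment scales with the clinical deficit (66 - score); the
        # same mapping applies at both timepoints, so any time effect in
        # the quality metrics enters only through score improvement (the
        # study saw stable direction patterns over time).
        deficit = 66 - fma_ue
        return ImpairmentProfile.from_scalars(
            completion_prob=float(np.clip(0.99 - 0.002 * deficit, 0.9, 1.0)),
            time_scale=1.02 + 0.018 * deficit,
            ap_gain=0.30,
            extra_submovements=0.15 + 0.055 * deficit,
            ml_bias=0.5,
            hold_failure_prob=float(np.clip(0.03 + 0.002 * deficit, 0.0, 0.12)),
            noise_sd=0.03,
        )
    # moderate / severe, more-affected side
    comp = float(np.clip((fma_ue - 30.0) / 120.0, 0.0, 0.125))
    move = float(np.clip((fma_ue - 2.0) / 30.0, 0.02, 0.98))
    hold_fail = float(np.clip(0.70 - fma_ue / 50.0, 0.08, 0.65))
    completion = {}
    scale = {}
    for d in DIRECTION_ORDER:
        apness = abs(math.sin(math.radians(d.angle_deg)))
        completion[d] = comp * (1.0 - 0.3 * apness)
        scale[d] = 1.3 * (1.0 + 0.30 * apness)
    return ImpairmentProfile(
        completion_prob_by_direction=completion,
        time_scale_by_direction=scale,
        extra_submovements=2.0,
        ml_bias=ml_bias,
        hold_failure_prob=hold_fail,
        noise_sd=0.02,
        move_prob=move,
    )


# ---------------------------------------------------------------------------
# Trial simulation


def _flags_from_path(
    pos: np.ndarray,
    onset_idx: int,
    target: Direction,
    config: TaskConfig,
) -> Tuple[bool, bool, Optional[int]]:
    """Derive outcome flags geometrically from the generated path, using the
    same exit/entry rules the analysis applies by default."""
    d_center = np.hypot(pos[onset_idx:, 0], pos[onset_idx:, 1])
    left_center = bool(np.any(d_center > config.exit_radius))
    tgt = config.target_distance * direction_unit_vector(target)
    d_tgt = np.hypot(pos[onset_idx:, 0] - tgt[0], pos[onset_idx:, 1] - tgt[1])
    hits = np.nonzero(d_tgt <= config.peripheral_radius)[0]
    hits = hits[hits <= config.reach_limit]
    if hits.size == 0:
        return left_center, False, None
    return left_center, True, int(hits[0])


def simulate_trial(
    profile: ImpairmentProfile,
    target: Optional[Direction],
    config: TaskConfig = TaskConfig(),
    seed: RngLike = None,
    geometry: ArmGeometry = ArmGeometry(),
    recorded_arm: str = "left",
    trial_index: int = 0,
) -> TrialRecord:
    """Simulate one trial of the reaching state machine.

    Emits the hold phase (uniform 1,250-1,750 ms with low-pass-filtered
    baseline jitter); then either a hold failure (no target), a completed
    reach within the time limit, a slow reach truncated by the limit, a
    stalled trial of centre-leaving sub-excursions with mediolateral/
    anteroposterior energy split set by ``ml_bias``, or no movement at all.
    Positions are quantized to the protocol's 0.01-cm resolution and
    outcome flags are derived geometrically from the quantized path.
    """
    rng = _rng(seed)
    rate = config.sample_rate
    center = np.zeros(2)
    hold_n = int(rng.integers(config.hold_min, config.hold_max + 1))
    hold_fail = rng.random() < profile.hold_failure_prob

    if target is None or hold_fail:
        dead = int(rng.integers(400, 801))
        ideal = np.tile(center, (hold_n + dead, 1))
        onset_idx: Optional[int] = None
        shown: Optional[Direction] = None
    else:
        shown = target
        onset_idx = hold_n
        tgt = config.target_distance * direction_unit_vector(target)
        u_hat = tgt / np.hypot(*tgt)
        moves = rng.random() < profile.move_prob
        completes = moves and (
            rng.random() < profile.completion_prob_by_direction[target]
        )
        if not moves:
            reach = np.tile(center, (config.reach_limit, 1))
        elif completes and rng.random() < 0.03:
            # Attentional/effort lapse: the reach is attempted but far too
            # slow, so the time limit truncates it (left centre, timed out).
            dur = rng.uniform(3300.0, 4500.0)
            path = minimum_jerk_reach(center, tgt, dur, rate)
            reach = path[: config.reach_limit]
        elif completes:
            dur = rng.uniform(600.0, 1050.0) * profile.time_scale_by_direction[target]
            lam = profile.extra_submovements * profile.time_scale_by_direction[target]
            k = int(rng.poisson(lam))
            k = min(k, max(0, int((2800.0 - dur) / 320.0)))
            amp = rng.uniform(0.55, 1.05)
            if k > 0:
                # Endpoint of the main reach sits so that the cursor crosses
                # the target boundary after the final correction's speed
                # peak (the last peak must fall inside [onset, offset]).
                r_fin = 1.0 - 0.45 * amp + rng.uniform(0.0, 0.10)
            else:
                r_fin = rng.uniform(0.15, 0.60)
            end = tgt - r_fin * u_hat
            base = minimum_jerk_reach(center, end, dur, rate)
            path = add_submovements(
                base, k, amplitude=amp, seed=rng, rate=rate, lateral=1.0
            )
            settle = np.tile(path[-1], (int(rng.integers(80, 151)), 1))
            reach = np.vstack([path, settle])
        else:
            # Incomplete mover: sub-excursions leaving and re-entering the
            # centre region, axis energy split by ml_bias.
            segs: List[np.ndarray] = []
            t_used = 0
            n_exc = int(rng.integers(3, 8))
            p_cur = center.copy()
            # Error-diffused axis allocation: the mediolateral share of
            # excursions tracks ml_bias with far less sampling noise than
            # independent Bernoulli draws, so a participant's pooled
            # proportion is a stable expression of the latent bias.
            acc = rng.random()
            for _ in range(n_exc):
                acc += profile.ml_bias
                if acc >= 1.0:
                    axis = 0
                    acc -= 1.0
                else:
                    axis = 1
                amp = rng.uniform(3.5, 6.5) * (1.0 if rng.random() < 0.5 else -1.0)
                peak = center.copy()
                peak[axis] += amp
                leg = int(rng.integers(250, 451))
                ret = center + rng.normal(0.0, 0.05, size=2)
                out = minimum_jerk_reach(p_cur, peak, leg, rate)
                back = minimum_jerk_reach(peak, ret, leg, rate)
                pause = int(rng.integers(80, 201))
                segs.append(out[1:])
                segs.append(back[1:])
                segs.append(np.tile(ret, (pause, 1)))
                p_cur = ret
                t_used += 2 * leg + pause
                if t_used > config.reach_limit:
                    break
            reach = np.vstack(segs)[: config.reach_limit]
        ideal = np.vstack([np.tile(center, (hold_n, 1)), reach])

    noise = _smooth_noise(ideal.shape[0], profile.noise_sd, rate, rng)
    pos = ideal + noise
    q = config.spatial_resolution
    pos = np.round(pos / q) * q

    if onset_idx is None:
        left_center, reached, entry = False, False, None
    else:
        left_center, reached, entry = _flags_from_path(pos, onset_idx, shown, config)

    shoulder, elbow = joint_angles_from_hand(
        pos, geometry, center, trial_index=trial_index
    )
    if recorded_arm == "right":
        pos = pos.copy()
        pos[:, 0] = -pos[:, 0]
    return TrialRecord(
        trial_index=trial_index,
        target=shown,
        t_ms=np.arange(pos.shape[0], dtype=np.int32),
        hand_xy=pos,
        shoulder_deg=shoulder,
        elbow_deg=elbow,
        target_onset_ms=onset_idx,
        left_center=left_center,
        reached_target=reached,
        reach_duration_ms=entry,
        recorded_arm=recorded_arm,
        center_xy=(0.0, 0.0),
    )


def blocked_schedule(
    n_trials: int, rng: np.random.Generator
) -> List[Direction]:
    """Blocked-random target schedule: every consecutive block of 8
    scheduled trials contains each direction exactly once."""
    if n_trials % len(DIRECTION_ORDER) != 0:
        raise ValueError("n_trials must be a multiple of 8")
    labels: List[Direction] = []
    for _ in range(n_trials // len(DIRECTION_ORDER)):
        block = [DIRECTION_ORDER[i] for i in rng.permutation(len(DIRECTION_ORDER))]
        labels.extend(block)
    return labels


def simulate_session(
    participant_id: str,
    side: str,
    timepoint: str,
    recorded_arm: str,
    fma_ue: int,
    profile: ImpairmentProfile,
    config: TaskConfig = TaskConfig(),
    seed: RngLike = None,
    geometry: ArmGeometry = ArmGeometry(),
) -> ParticipantSession:
    """Simulate one participant x side x timepoint session of scheduled
    trials under a blocked-random schedule."""
    if isinstance(seed, np.random.SeedSequence):
        seed_key: Optional[List[int]] = [int(s) for s in seed.entropy] if isinstance(
            seed.entropy, (tuple, list)
        ) else None
        rng = np.random.default_rng(seed)
    else:
        seed_key = [seed] if isinstance(seed, int) else None
        rng = _rng(seed)
    schedule = blocked_schedule(config.n_trials, rng)
    trials = [
        simulate_trial(
            profile,
            tgt,
            config,
            seed=rng,
            geometry=geometry,
            recorded_arm=recorded_arm,
            trial_index=i,
        )
        for i, tgt in enumerate(schedule)
    ]
    return ParticipantSession(
        participant_id=participant_id,
        side=side,
        timepoint=timepoint,
        recorded_arm=recorded_arm,
        fma_ue=fma_ue,
        trials=trials,
        seed=seed_key,
    )


# ---------------------------------------------------------------------------
# Cohort generation


@dataclass(frozen=True)
class CohortSpec:
    """Sampling plan for a synthetic cohort.

    Clinical-score distributions default to the study population this
    generator emulates: 13 mild participants (admission FMA-UE 59.0 +/- 5.7,
    mean improvement 3.3) and 15 moderate-to-severe participants (19.4 +/-
    14.4, mean improvement 9.5); improvement SDs are back-derived from the
    reported paired t statistics and draws are clipped at zero so discharge
    is never worse than admission.  The mediolateral excursion bias of
    incomplete movers defaults to 68.6% at admission, recovering by 6.9
    points on average at discharge.
    """

    n_mild: int = 13
    n_severe: int = 15
    mild_fma_mean: float = 59.0
    mild_fma_sd: float = 5.7
    severe_fma_mean: float = 19.4
    severe_fma_sd: float = 14.4
    mild_improvement_mean: float = 3.3
    mild_improvement_sd: float = 4.8
    severe_improvement_mean: float = 9.5
    severe_improvement_sd: float = 6.7
    ml_bias_admission: float = 0.686
    ml_bias_sd: float = 0.045
    ml_bias_recovery_mean: float = 0.069
    ml_bias_recovery_sd: float = 0.03
    prob_left_affected: float = 0.64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mild < 0 or self.n_severe < 0:
            raise ValueError("cohort sizes must be nonnegative")
        if not 0.0 <= self.prob_left_affected <= 1.0:
            raise ValueError("prob_left_affected must lie in [0,1]")


@dataclass(frozen=True)
class Participant:
    """Roster entry: sampled scores and latent generator parameters."""

    participant_id: str
    index: int
    group: SeverityGroup
    affected_arm: str  # "left" | "right"
    fma_admission: int
    fma_discharge: int
    ml_bias_admission: float
    ml_bias_discharge: float


def _sample_int_clipped(
    rng: np.random.Generator, mean: float, sd: float, lo: int, hi: int
) -> int:
    return int(np.clip(round(rng.normal(mean, sd)), lo, hi))


def cohort_participants(spec: CohortSpec) -> List[Participant]:
    """Sample the cohort roster (deterministic in ``spec.seed``)."""
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 0)))
    roster: List[Participant] = []
    idx = 0
    for _ in range(spec.n_mild):
        adm = _sample_int_clipped(rng, spec.mild_fma_mean, spec.mild_fma_sd, 46, 66)
        gain = max(0.0, rng.normal(spec.mild_improvement_mean, spec.mild_improvement_sd))
        dis = int(np.clip(adm + round(gain), adm, 66))
        arm = "left" if rng.random() < spec.prob_left_affected else "right"
        roster.append(
            Participant(
                participant_id=f"P{idx + 1:02d}",
                index=idx,
                group=SeverityGroup.MILD,
                affected_arm=arm,
                fma_admission=adm,
                fma_discharge=dis,
                ml_bias_admission=0.5,
                ml_bias_discharge=0.5,
            )
        )
        idx += 1
    for _ in range(spec.n_severe):
        adm = _sample_int_clipped(rng, spec.severe_fma_mean, spec.severe_fma_sd, 3, 45)
        gain = max(
            0.0, rng.normal(spec.severe_improvement_mean, spec.severe_improvement_sd)
        )
        dis = int(np.clip(adm + round(gain), adm, 45))
        bias_adm = float(np.clip(rng.normal(spec.ml_bias_admission, spec.ml_bias_sd), 0.5, 0.85))
        recovery = max(
            0.0, rng.normal(spec.ml_bias_recovery_mean, spec.ml_bias_recovery_sd)
        )
        bias_dis = float(np.clip(bias_adm - recovery, 0.5, 0.85))
        arm = "left" if rng.random() < spec.prob_left_affected else "right"
        roster.append(
            Participant(
                participant_id=f"P{idx + 1:02d}",
                index=idx,
                group=SeverityGroup.MODERATE_TO_SEVERE,
                affected_arm=arm,
                fma_admission=adm,
                fma_discharge=dis,
                ml_bias_admission=bias_adm,
                ml_bias_discharge=bias_dis,
            )
        )
        idx += 1
    return roster


_SIDES = ("less_affected", "more_affected")  # task order: less-affected first
_TIMEPOINTS = ("admission", "discharge")


def session_seed(spec_seed: int, participant_index: int, side: str, timepoint: str) -> np.random.SeedSequence:
    """Documented counter scheme expanding the cohort seed per session."""
    return np.random.SeedSequence(
        (
            spec_seed,
            1,
            participant_index,
            _SIDES.index(side),
            _TIMEPOINTS.index(timepoint),
        )
    )


def iter_cohort_sessions(
    spec: CohortSpec,
    config: TaskConfig = TaskConfig(),
    geometry: ArmGeometry = ArmGeometry(),
) -> Iterator[Tuple[Participant, ParticipantSession]]:
    """Generate the cohort lazily, one session at a time.

    Yields two sides x two timepoints per participant; the less-affected
    side uses a near-healthy profile, the more-affected profile follows the
    sampled clinical score, and discharge profiles are never worse than
    admission.
    """
    for person in cohort_participants(spec):
        for timepoint in _TIMEPOINTS:
            fma = (
                person.fma_admission
                if timepoint == "admission"
                else person.fma_discharge
            )
            ml_bias = (
                person.ml_bias_admission
                if timepoint == "admission"
                else person.ml_bias_discharge
            )
            # Mild-group kinematic profiles are anchored to the admission
            # score: the study's quality metrics and their direction
            # patterns stayed stable over the stay even though the clinical
            # score improved.  The moderate-to-severe mapping follows the
            # improving score (movement capacity did expand).
            profile_fma = (
                person.fma_admission if person.group is SeverityGroup.MILD else fma
            )
            for side in _SIDES:
                recorded_arm = (
                    person.affected_arm
                    if side == "more_affected"
                    else ("right" if person.affected_arm == "left" else "left")
                )
                profile = impairment_profile(
                    profile_fma, side, timepoint, ml_bias=ml_bias
                )
                ss = session_seed(spec.seed, person.index, side, timepoint)
                yield person, simulate_session(
                    participant_id=person.participant_id,
                    side=side,
                    timepoint=timepoint,
                    recorded_arm=recorded_arm,
                    fma_ue=fma,
                    profile=profile,
                    config=config,
                    seed=ss,
                    geometry=geometry,
                )


def simulate_cohort(
    spec: CohortSpec,
    config: TaskConfig = TaskConfig(),
    geometry: ArmGeometry = ArmGeometry(),
) -> List[ParticipantSession]:
    """Materialize the full cohort (4 sessions per participant)."""
    return [s for _, s in iter_cohort_sessions(spec, config, geometry)]
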