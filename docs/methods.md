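# Methods

## Task model and coordinate conventions

The task is a planar visually guided center-out reach: the cursor (0.4-cm
radius) is held inside a central target (1.0-cm radius) for a uniformly
random 1,250–1,750-ms hold; a peripheral target (1.0-cm radius) then
appears at 10 cm in one of eight directions spaced 45° apart, and the
participant has 3,000 ms to reach it. Sessions are 64 trials under a
blocked-random schedule (every consecutive block of 8 scheduled targets
covers all 8 directions once). Sampling is 1 kHz with positions quantized
to 0.01 cm. If the hold is broken, the trial counter advances without a
target ("no-target" trial).

All analysis happens in a common **left-arm frame**: +x toward the
participant's midline (medial), +y away from the body (forward).
Direction labels (M, MF, F, LF, L, LB, B, MB) are body-referenced, so
right-arm recordings are mirrored by negating x about the start position
while labels stay fixed. The reflection is an exact involution; mirroring
an already-left trial is the identity. Absolute room orientation is
internal — only relative directions carry meaning.

## Per-trial metrics

* **Speed** is the magnitude of the central-difference derivative of the
  quantized hand position (one-sided at the ends).
* **Thresholds**: all per-millisecond speed samples from the 500-ms
  windows preceding each target illumination in a session are pooled; the
  lower threshold is the pooled median and the upper the pooled 95th
  percentile (linear interpolation between closest ranks). A per-trial
  variant (median of per-trial statistics) is available by option because
  the pooling convention is a genuine ambiguity; pooled is the default.
* **Onset**: from the first post-illumination sample at which the cursor
  leaves the centre (centre distance > central radius + cursor radius =
  1.4 cm), scan backward toward illumination and return the first sample
  that is (a) a strict local speed minimum below the upper threshold or
  (b) below the lower threshold; if the scan exhausts, the illumination
  time is returned and flagged as a fallback. Onset uses *unfiltered*
  speed; only peak counting uses the filtered profile.
* **Offset**: first post-illumination sample with the cursor inside the
  peripheral target. The default entry rule is "cursor centre within the
  target circle" (distance ≤ 1.0 cm); a circle-overlap rule (≤ 1.4 cm) is
  available by option since the display semantics are not fixed by the
  protocol constants.
* **Movement time** = offset − onset; **path length** = summed Euclidean
  sample-to-sample distance over [onset, offset].
* **Velocity peaks**: the speed series is filtered with an order-6
  Butterworth low-pass at 10 Hz applied forward and backward
  (`sosfiltfilt`; zero phase, squared magnitude response), then strict
  local maxima (greater than both neighbours, no amplitude/distance
  thresholds) are counted within [onset, offset]. Plateaus and window
  endpoints are never peaks. The filter needs > 21 samples; shorter series
  are rejected.
* **AP/ML displacement**: AP_total = Σ|Δy|, ML_total = Σ|Δx| over the
  span from illumination to the end of the outbound reach phase (target
  entry, the 3,000-ms limit, or the end of the recording) — the return to
  centre is a different behaviour and is excluded by default (a
  whole-recording option exists). The participant-level statistic is
  100·ML/(AP+ML) pooled over qualified trials; a participant with zero
  pooled displacement yields a missing value, not a zero.
* **Joint paths**: shoulder/elbow angles relative to the onset posture,
  linearly resampled onto a fixed 101-point 0–100% movement grid.

### Trial qualification

Quality arm: target shown ∧ reached ∧ reach duration ≤ 3,000 ms.
Quantity arm: target shown ∧ the hand left the centre. No-target trials
count in the denominators of exclusion percentages (the 64-trial counter
advances regardless); this is a documented choice, configurable in
reporting, since the original denominators are not specified.

## Group inference

* **Three-way RM ANOVA** (direction × side × time, all within
  participants) is computed from first principles as a balanced
  within-subject sum-of-squares decomposition (inclusion–exclusion over
  marginal means); each effect is tested against its interaction with
  subjects. The decomposition must conserve the total SS to 1e-8 and this
  is asserted at runtime. Per multi-level effect, Mauchly's W is computed
  from the covariance of orthonormal Helmert contrast scores with the
  plain chi-square approximation (as SPSS reports it; pingouin adds a
  second-order Box term, which is why its Mauchly *p* differs slightly
  while W and χ² agree); the Greenhouse–Geisser ε = tr(S)²/(q·tr(S²)) is
  clipped to [1/q, 1] and applied to both dfs only when Mauchly's P <
  0.05. When the number of subjects is too small for the contrast
  covariance to be full-rank (n − 1 ≤ q) the test is undefined and no
  correction is applied. Note that ε-shrunken dfs are conservative
  wherever the uncorrected P ≤ 0.2 (a numeric scan places every crossing
  of the two tail probabilities above P ≈ 0.23); below that the ordering
  is not mathematically guaranteed, which never affects a decision at any
  conventional α.
* **Mixed model**: ml% ~ side*time with a participant random intercept,
  effects (sum) coding, REML fit via statsmodels MixedLM with a
  derivative-free fallback when the variance component collapses.
  Denominator dfs are Satterthwaite: the variance-component covariance is
  the inverse expected information ½tr(P V̇ⱼ P V̇ₖ), and the delta method is
  applied to each coefficient variance. Cross-checked against lmerTest
  (which uses the observed information; agreement to ~0.2% on the df).
  The model tolerates missing cells without dropping participants; a
  random-intercept variance below 1e-8·residual flags a singular fit.
* **Paired t** on clinical scores, df = n − 1, two-sided; zero-variance
  differences are rejected.

## The synthetic cohort

The generator exists because no recordings are deposited; it produces
sessions with the statistical structure the analysis assumes, not a
biomechanical simulation. Defaults encode the study population it
emulates:

* 13 mild + 15 moderate-to-severe participants; admission FMA-UE scores
  N(59.0, 5.7²) clipped to 46–66 (mild) and N(19.4, 14.4²) clipped to
  3–45 (moderate-to-severe); mean improvements +3.3 and +9.5 with SDs 4.8
  and 6.7 back-derived from the reported paired t statistics, clipped at
  zero so discharge is never worse than admission (this clipping inflates
  the synthetic paired t statistics relative to a real cohort).
* Completed reaches are minimum-jerk paths with uniform 600–1,050-ms base
  durations, scaled per direction by 1 + 0.30·|sin θ| (θ the target angle
  from the mediolateral axis) — the anteroposterior deficit. Corrective
  submovements are discrete minimum-jerk steps appended through laterally
  alternating waypoints; their Poisson rate is
  extra_submovements × time_scale(direction), so one injected deficit
  drives all three quality metrics (time, path, smoothness) coherently.
  Each step contributes exactly one filtered-speed peak; waypoint
  geometry keeps every intermediate point outside the target and places
  target entry after the final step's speed peak, so the noiseless peak
  count is exactly 1 + k.
* Mild-group kinematic profiles are a deterministic function of the
  *admission* score at both timepoints: the study's quality metrics and
  their direction patterns were stable over the stay even though the
  clinical score improved, so time effects enter the quality arm only as
  sampling noise. The moderate-to-severe mapping follows the improving
  score (movement capacity did expand).
* Incomplete movers emit 3–7 out-and-back sub-excursions (3.5–6.5 cm,
  250–450-ms legs) along the mediolateral or anteroposterior axis. Axis
  choice is error-diffused (an accumulator with a random initial phase)
  rather than Bernoulli so a participant's pooled ML proportion expresses
  the latent `ml_bias` with ~1–2-point sampling noise instead of ~6; the
  per-participant bias is N(0.686, 0.045²) at admission, recovering by
  N(0.069, 0.03²) (clipped ≥ 0) at discharge. Completed-reach
  contamination and isotropic jitter bias the pooled proportion toward
  50% by well under a point at the default severe completion rates.
* A 3% "lapse" converts an otherwise-completing reach into a slow
  truncated attempt (timeout); hold failures and a `move_prob` gate
  (probability that a shown-target trial moves at all) emulate exclusion
  rates and the occasional participant with no scoreable trial.
* Baseline hold jitter is white positional noise low-passed at 5 Hz
  (SD 0.03 cm; 0.02 cm for severe profiles), so pre-illumination speed
  thresholds are nonzero and nondegenerate.
* Joint angles come from planar two-link inverse kinematics (elbow-down
  branch; links 30 + 33 cm, configurable — they affect only joint-angle
  outputs). The shoulder is positioned so the central target corresponds
  to 30° shoulder horizontal adduction and 90° elbow flexion.
* Reproducibility: the cohort seed expands as
  `SeedSequence((seed, 1, participant_index, side_index, time_index))`
  per session and `SeedSequence((seed, 0))` for the roster, so any single
  session regenerates in isolation.

**What passing tests show — and don't.** The generator's trials are
smooth, piecewise minimum-jerk, with stationary noise and hard
state-machine boundaries. Real hemiparetic reaching has tremor,
co-articulated corrections, drifting baselines, and trunk-strap artifacts
none of which are modelled; EMG, torque, and trunk compensation are out
of scope. Passing the recovery suites demonstrates that the *pipeline*
measures what it claims (detectors match oracles exactly; injected
parameters are recovered within stated tolerances; the statistical engine
matches independent implementations), not that the cohort statistics of
any real population are reproduced.

## Problem sizes and numerical choices

Replicate-based checks run at reduced but fixed sizes chosen to keep the
suites comfortably convergent: the null-calibration of the ANOVA uses 500
replicates of an 8×2×2 design with 8 subjects; the cohort-signature
recovery uses 50 replicates of a 13-participant mild cohort with 40-trial
sessions; detector–oracle equivalence uses 1,000 trials with shortened
(550–700-ms) holds, which leaves the 500-ms threshold window intact. The
full default cohort (28 participants, 112 sessions, 64-trial sessions at
1 kHz) generates and analyzes in well under a minute.

Ties and degenerate inputs: strict inequalities define local extrema, so
plateaus are neither peaks nor minima; a session whose every trial lacks
a target cannot form thresholds and contributes no quality metrics; an
all-equal response vector is rejected by the mixed model; FMA scores must
be integers in 0–66 (no rounding of fractional input).
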