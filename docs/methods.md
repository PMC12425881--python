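# Methods

This package implements an offline analysis pipeline for simultaneous and
proportional myoelectric position control: decoding the continuous position
of several hand/wrist degrees of freedom (DOFs) from surface EMG of a
paretic forearm, and asking how many DOFs remain controllable as more are
added.  Because raw patient EMG of this kind is not publicly available, the
pipeline is exercised end to end on a synthetic cohort whose generative
model is described below, and the published per-participant results are
carried as reference tables for the functional-control classification.

## Task structure and targets

A session cues eight movements — full-hand close/open (HC/HO), tripod
close/open (TC/TO), wrist flexion/extension (WF/WE), pronation/supination
(WP/WS) — spanning four DOF axes (hand, tripod, wrist pitch, wrist roll).
Each attempt is a trapezoid at the 30-Hz kinematic rate: a 0.7-s linear
rise from rest to the peak, a 3-s hold, and a 0.7-s fall, followed by 3 s
of rest; ten repetitions per movement per session, two sessions
(train/test).

Discretization: the rise occupies `round(0.7 * 30) = 21` samples with
values k/21 (k = 1..21, so the final rise sample is the peak), the hold
`round(3 * 30) + 1 = 91` samples at the peak, and the fall mirrors the
rise — 133 samples per attempt.  Under this convention the RMS of the unit
trapezoid is sqrt(106.016/133) = 0.8928, which is the intended-movement
RMSE of predicting rest throughout a movement; this 0.893 baseline anchors
the whole error scale (a useful decoder must sit far below it).

Position encoding: +1 is maximum flexion/close/pronation, −1 maximum
extension/open/supination, 0 rest.  Unidirectional control treats each
movement as its own DOF column with targets in [0, 1] (magnitude
encoding); bidirectional control maps a movement pair onto one signed
column in [−1, 1].

## Synthetic session model (`synth`)

The generator emits 30-Hz MAV-level features directly.  For electrode e at
time t:

    MAV_e(t) = baseline_e + [ sum_m  S_{m,e} * g_m * a_m(t - lag) ] * c_e + noise

- `S` (8 x 32) is the synergy matrix: each movement has a disjoint dominant
  electrode subset (weights U(0.5, 1.5)), mixed with a diffuse positive
  background in proportion to the `crosstalk` parameter.
- `a_m(t)` is the activation drive: the instructed trapezoid envelope on
  the cued movement, plus `crosstalk` times that envelope co-activating
  every other movement's synergy — the paretic co-activation the analysis
  has to be robust to.
- `g_m` is an optional per-movement gain (default 1) for weakening, e.g.,
  extensor movements.
- `lag` is the participant's reaction time: the EMG lags the instructed
  kinematics (default 200 ms).
- `c_e ~ lognormal(0, session_gain_sd)` is per-channel multiplicative gain
  drift drawn independently per session (default sd 0.1), making the two
  sessions of a participant non-identical.
- `noise ~ N(0, noise_sd)` (default 0.05), with the result truncated at 0
  (MAV is non-negative).

Defaults — crosstalk 0.2, noise_sd 0.05, baseline 0.1, lag 200 ms,
session_gain_sd 0.1 — were chosen once as a plausible moderately-impaired
operating point on the scale where a held movement drives its dominant
electrodes at ~0.5–1.5 MAV units.  Participants of the default cohort
differ only by seed (hence by synergy layout, drift and noise draws).

What the generator does *not* emulate: motor-unit firing statistics,
spasticity dynamics, electrode shift, sweat/motion artifacts, fatigue, or
any quantitative match to patient EMG distributions.  Passing tests on
this cohort demonstrate the pipeline's correctness and its qualitative
degradation behavior, not clinical performance.

An optional raw mode synthesizes 1-kHz band-limited noise amplitude-
modulated by the same envelopes, used only to exercise the filtering front
end.

## Feature construction (`preprocess`)

Raw-mode signals are band-pass filtered 15–375 Hz (4th-order Butterworth)
and notch-filtered at 60/120/180 Hz (2nd-order IIR, Q = 30), causally
(forward-only, matching a real-time implementation).  The 32 single-ended
channels are expanded with all 496 pairwise differences to 528 channels —
on the time-domain signals, before rectification, since the MAV of a
difference is not the difference of MAVs.  MAV uses trailing (causal)
300-ms windows emitted at 30 Hz, early windows shrinking to the available
history.  When the input is already MAV-level (the generator's default),
the pairwise expansion is applied to the MAV signals directly and the
filter/MAV stages are skipped.

The per-channel mean resting MAV is subtracted before training and testing
(negatives permitted afterwards).  One scalar reaction-time lag per
session is estimated by maximizing, over lags 0..500 ms, the
summed-over-axes correlation between |kinematics| and the feature envelope
(features summed over the single-ended channels); the kinematics and
labels are then delayed by that lag, with rest padding the vacated
samples.  All-zero inputs are flagged degenerate and get lag 0.

## Channel selection (`selection`)

528 channels are reduced to k = 48 by stepwise Gram-Schmidt selection
(forward orthogonal least squares).  Features and targets are
mean-centered; at each step every unselected channel is scored by the
squared correlation of its residual (component orthogonal to the selected
span) with the target residuals, summed over target axes — the classical
error-reduction ratio.  The argmax is appended; channels and targets are
orthogonalized against it.  Channels whose residual norm falls below 1e-10
of their original norm are skipped (this removes exact duplicates and
constants); ties break toward the lowest index for determinism.  Selection
is fit on the training session only and the indices reused on the test
session.  Scoring against all target axes jointly (rather than per-DOF)
is a design choice; so is orthogonalizing the targets alongside the
channels.

## Decoder (`decoder`)

A linear Kalman filter with state x_t = [positions_t; 1] — no velocity
states; the constant-1 element absorbs feature offsets that survive
baseline subtraction.  Training is least squares on 100% of the first
session: A from the one-step state regression X2 ≈ A X1 with W the
residual covariance (the constant row of A is pinned to [0..0, 1] exactly,
with zero process noise); H from the feature-on-state regression Z ≈ H X
with Q the residual covariance.  A trace-scaled ridge (1e-6) stabilizes
both normal equations.  Q additionally receives a small diagonal floor
(1e-8-scaled): on noiseless data the observation regression is exact,
Q -> 0, and the innovation covariance S = H P⁻ Hᵀ + Q (rank at most
state_dim << k) would be singular.

Prediction is the standard recursion from the rest state [0..0, 1] with
P = W, the constant element re-pinned to 1 after each update and P
symmetrized each step.  The "modified" output applies, per sample and per
DOF (non-latching), a dead-band — zero until |raw| exceeds 0.2 — followed
by clipping to [−1, 1].  The dead-band suppresses small unintended
deflections at the cost of a floor on intended error: on the default
trapezoid the 8 rise/fall samples below 0.2 contribute ~0.032 RMSE even
for an otherwise perfect decoder, which is why the noiseless end-to-end
check allows up to 0.05.

## Evaluation (`metrics`)

Per attempt (the 133-sample trapezoid; inter-trial rest excluded):

- intended RMSE = sqrt(mean over H samples and M_m moving DOFs of the
  squared target-prediction difference);
- unintended RMSE (xRMSE) = sqrt(mean over H samples and M_s stationary
  DOFs of the squared prediction) — already averaged across stationary
  DOFs, one value per attempt; absent (None, never 0) when D = 1.

Aggregation: mean over the 10 attempts per movement, mean over movements
per combination, median across participants for group summaries.  The
within-participant reduction (means) is a recorded choice.

Functional control: intended <= 0.45 AND xRMSE <= 0.04, inclusive.
Inclusivity is forced by the reference tables themselves: the published
3-DOF row sitting exactly at xRMSE = 0.04 is counted among the four
functional participants, which a strict comparison would contradict.  Best
combination per participant: minimize intended + unintended, ties broken
by lower unintended, then lexicographic name.

Group comparisons delegate to scipy: Kruskal-Wallis for independent
groups, Wilcoxon signed-rank for paired designs (all-zero differences are
returned as a flagged degenerate result).

## Study orchestration (`experiment`)

Combination levels: 8 single unidirectional movements; 4 bidirectional
opposing pairs; 2-DOF = {HC,TC} x {WF,WE,WP,WS} (8); 3-DOF = {HC,TC} x
{WF,WE} x {WP,WS} (8); 4-DOF = HC and TC together x {WF,WE} x {WP,WS}
(4).  For each participant x combination, both sessions are subset to the
combination's movements plus surrounding rest; baseline subtraction and
lag alignment are recomputed per session; selection and training see the
training session only (asserted via the audit log).  The master seed fans
out to per-participant seeds through `numpy.random.SeedSequence.spawn`,
and reruns are byte-identical.

Problem sizes: the default cohort is 7 participants x 2 sessions of
17,930 samples (about 10 min of recording each) x 32 combinations, which
completes in a few minutes on one CPU.  The noise-robustness sweep uses
single-movement sessions (20 seeds x 5 noise levels) for the same reason.

## Known limitations

- The synthetic co-activation is linear and stationary; real paretic
  co-activation is task- and fatigue-dependent.
- The dead-band/clip pair is the only post-hoc output modification
  implemented; other modifications used with this decoder family in prior
  work are out of scope.
- Published per-participant RMSE values cannot be reproduced without the
  original patient recordings; only their functional classification (and
  the resulting counts and percentages) is asserted.
- With the default generator the synthetic cohort is easier than real
  patients: all participants remain functional at every level.  The cohort
  is built to exercise ordering properties (noise monotonicity,
  non-increasing functional share with added DOFs), not absolute rates.
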