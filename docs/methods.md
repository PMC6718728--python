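# Methods

## Problem setting

A simultaneous-and-proportional myocontroller maps surface-EMG features to
four prediction signals in [0, 1], one per controlled degree of freedom of
a six-motor prosthetic hand (thumb flexion, index flexion, the coupled
middle/ring/little flexion, thumb rotation). Predictions above an
actuation threshold command proportional closing; below it the hand is
driven to the fully open home configuration. A *failure* is a discrete
event: the first instant at which the hand starts a behavior contrary to
the user's intent (a spurious closing movement while the user rests, or a
spurious opening while the user holds a grasp). The package detects such
events from windowed count features using a class-weighted SVM and
provides the surrounding evaluation and statistics machinery, exercised
end-to-end on a ground-truth simulator.

## Data model and conventions

- Time is session-absolute seconds; both traces share one uniform sample
  grid (default 100 Hz, configurable — the feedback rate of the hand's
  digit-status flags is not standardized, so statuses are assumed
  resampled onto the prediction timebase).
- Each task timeline carries `t_start < t_grasp < t_release < t_end`.
  Zones are half-open on the right: the grasp instant itself belongs to
  the Grasp zone, so zones partition the task exactly.
- Windows are half-open `[start, end)`, tiled per task from `t_start` with
  step = length (no overlap) or length/2 (half overlap); a trailing
  partial window is dropped so counts stay comparable across window sizes.
  Windows never span task boundaries (tasks are separated by seated
  pauses).
- Samples exactly at the threshold count as *below* it — a deterministic
  tie-break used identically by the feature counter and the simulator's
  ground-truth crossing detector.
- Digit-status binarization: CLOSING/CLOSED → flexing (1), OPENING/OPEN →
  extending (0), STALLED → hold the previous binary value (an initial
  stall reads as extending). A stall preserves the last motion direction;
  mapping it to either fixed value would manufacture spurious status
  changes. The six digits collapse to the four prediction channels
  through representative digits (thumb, index, middle-for-the-coupled-
  triple, rotator).
- Serialization is plain CSV (traces) + JSON (metadata) with repr-level
  float precision, so a write/read round trip is the identity.

## Classifier

RBF-SVM with per-class regularization weights `C·w_class`:
`w_success = 1`, `w_failure = n₀/n₁` computed from the training labels.
The failure class is the label 1 and the minority class; the weight ratio
is the standard remedy for class skew, and grows automatically as longer
windows shrink the dataset and the imbalance changes.

Nested stratified 10-fold cross-validation: the inner 10-fold grid search
minimizes mean inner balanced error rate over `C ∈ {2⁻⁵, 2⁻³, …, 2¹⁵}`,
`γ ∈ {2⁻¹⁵, 2⁻¹³, …, 2³}` (powers of four — the customary coarse libsvm
grid; the original study's grid is unstated, so these are declared
defaults, not reconstructions). Ties prefer smaller C, then smaller γ
(smoother models). The winner is refit on the outer training set with
weights from the outer-training labels and applied to the held-out fold.
Counts are standardized with outer-training mean/variance only — raw
counts from different window lengths are not scale-comparable under an
RBF kernel. Folds are stratified and seeded: at the imbalance levels the
longer windows produce, unstratified folds can degenerate to a single
class, which the procedure could not tolerate.

Evaluation takes *success* as the positive condition. The pooled outer
confusion matrix gives the rate matrix (rows normalized by condition) and
BER = 100/2·(FNR + FPR). ROC curves use the SVM decision values, oriented
toward success — any strictly monotone transform of the scores (such as a
probability calibration) leaves the curve and AUC unchanged, and decision
values avoid the internal cross-validation nondeterminism of Platt
scaling. AUC equals the normalized Mann-Whitney U statistic with ties
counted one half. Mean ROC curves are vertical averages (mean TPR on a
fixed 101-point FPR grid, linear interpolation).

## Statistics layer

- **Zone summaries**: failures are assigned to zones via the half-open
  convention; within-zone positions are normalized by zone duration and
  binned (10 bins per zone by default) so tasks of different durations are
  comparable.
- **Trend + influence**: ordinary least squares with per-point Cook's
  distances (equal, and tested equal, to the leave-one-out refit
  definition). An exactly collinear point set is a perfect fit; its
  Cook's distances are defined as zero rather than the 0/0 of the
  closed form.
- **Group comparison**: Shapiro–Wilk per group, then the two-sided
  Wilcoxon rank-sum test; exact null distribution for combined n ≤ 25,
  normal approximation with continuity correction above.
- **ANOVA**: three-way fixed effects (feature type × window length ×
  overlap, all interactions) on a balanced full-factorial BER table;
  balance is required and validated — on a balanced design sequential and
  partial sums of squares coincide, and silently reweighting an
  unbalanced table would change the hypotheses. One-way reduction to
  feature type plus Tukey HSD follows. An effect whose sum of squares
  vanishes at the response scale is reported as F = 0, p = 1 (a constant
  response otherwise yields 0/0 noise).
- **Power**: fixed-effects special/main-effect convention,
  `λ = f²·N`, `df_den = N − k` for k design cells,
  `power = P(F′(df_num, df_den, λ) > F_crit(1−α))`, with Cohen's
  `f = √(SS_effect/SS_error)`. A-priori sample sizes are found by
  incrementing N from the smallest feasible design; no rounding to
  group-size multiples. One published reference value (158 for
  f = 0.2496 at α = 0.05) sits one unit below this search's answer (159,
  where power(158) = 0.7997); the discrepancy is a rounding convention of
  the original power software and the search result is reported as
  computed.

## Session simulator

The simulator emulates the study conditions, not any particular subject:

- **Tasks**: 20 per session by default; zone durations are truncated
  normals with means 5 s (Pre-Grasp), 8 s (Grasp), 12 s (Post-Grasp) —
  the Post-Grasp zone is the longest, as observed experimentally; exact
  durations were never published, so these are realistic desk-scale
  choices. 2 s seated pauses separate tasks.
- **Prediction dynamics**: flexion channels ramp smoothly (0.3 s) between
  a rest level of 0.05 and a grasp level of 0.7; band-limited Gaussian
  noise (SD 0.02) is added and clipped so that intent-conforming samples
  never cross the 0.3 threshold — only intended actuation ramps and
  injected transients may cross it.
- **Failures**: per task and zone, counts are Poisson with intensities
  (0.65, 0.65, 1.7) events/task — a 1 : 1 : 2.5 Pre:Grasp:Post ratio
  totalling ≈ 3 failures/task, qualitatively matching the published
  per-zone pattern (those figures are plotted, not printed, so the
  defaults are calibrated to the reported range, not to exact values).
  Post-Grasp times concentrate mid-zone (Beta(2,2)); other zones are
  uniform. Each event injects a windowed 3 Hz oscillatory transient
  (amplitude 0.5, duration 1 s) that drives one channel across the
  threshold against intent — upward on a resting channel (spurious
  close), downward on a grasping flexion channel (spurious open). The
  recorded ground-truth time is the first sample at which the transient
  actually crosses the threshold: the machine-observable analogue of the
  "first video frame" annotation rule.
- **Hand model**: below threshold each digit opens at the full digit
  speed (1 travel/s); above it, closing speed is proportional to the
  excess. During the grasp the held object blocks the five digit motors
  at 60% closure, producing STALLED statuses. Coupled digits share their
  command channel.
- **Buttons**: each failure is noticed with probability 0.8; a noticed
  failure yields a press after a truncated-normal delay (mean 1.5 s,
  SD 0.5 s). Failures within 3 s after a press are absorbed — one
  mechanism covering the no-repeat-signalling, structural-delay and
  failures-during-delay behaviors of real reporters.
- **Reproducibility**: each subsystem draws from
  `default_rng([stream, seed])` with fixed stream keys; a session is
  bit-identical across runs and platforms for a given config.

What the simulator does *not* emulate: real sEMG waveforms and their
nonstationarity, regression-model drift and incremental retraining,
catastrophic task aborts, posture- and fatigue-dependent failure
clustering, or annotation noise in the ground truth itself. Passing tests
therefore demonstrate the correctness and internal consistency of the
pipeline and that clean oscillatory instability is detectable; they do not
certify detection rates on real amputee data, where the published balanced
error rates (~19%) are far above this simulator's (~2%).

## Problem sizes and numerical choices

Tests and examples run one simulated subject with 20 tasks at 100 Hz
(unit tests use 6 tasks at 50 Hz), the full 11 × 10 hyperparameter grid
for the headline benchmark and a reduced 2 × 2 grid where only the CV
mechanics are under test. Window tiling uses an epsilon of 1e-9 on the
step arithmetic to absorb float drift; sample membership of a window is
`ceil(start·rate) ≤ i < ceil(end·rate)`. Dataset preconditions (≥ 10
instances per class for 10-fold stratification, both classes present for
weights/ROC) are enforced with explicit degenerate-data errors rather
than silent fallbacks.
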