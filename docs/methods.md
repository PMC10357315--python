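# Methods

## Problem and pipeline

Spatiotemporal gait parameters (stride length, cadence, swing/stance
percentages, double support, …) are sensitive markers of neurodegenerative
disease, but extracting them from contactless depth-camera recordings
requires locating gait events precisely in time.  `gaitpipe` implements a
two-stage approach:

1. **Per-frame gait-state classification.**  Each 30 Hz skeleton frame is
   labeled with one of five states — standstill (S), left swing (L), double
   support (D), right swing (R), turnaround (T) — by a classifier over 32
   spatiotemporal features (27 per-joint per-axis speeds, pelvis depth,
   knee separation, two pelvis–foot distances, waist-rotation angle).
2. **Rule-based segmentation and validation.**  The label stream is sliced
   into 7 transition events (gait semantics); the gait pair mechanism (GPM)
   retains only chains of 4 consecutive foot events obeying the legal cyclic
   order L_up → L_down → R_up → R_down (any rotation) outside turnarounds.
   The 18 parameters are computed per validated cycle (or per adjacent
   cycle pair) and averaged.

The validation stage is what makes the method robust: classification errors
near state transitions produce illegal event orderings, which the GPM
discards instead of letting them corrupt the parameter averages.

## Parameter definitions

All distances use the Euclidean metric on 3-D ankle positions at event
frames; `T(·)` denotes the event frame's timestamp.

| parameter | definition |
|---|---|
| Speed | mean pelvis displacement ÷ duration per straight interval |
| L/R Stride | ankle distance between two successive same-foot landings (adjacent cycle pair) |
| L/R Cycle | time between those landings |
| L/R StrideSpeed | stride ÷ cycle |
| L/R Cadence | 120 ÷ cycle (a cycle contains two steps) |
| L/R Step | landing to immediately preceding opposite-foot landing |
| L/R Swing % | (T(down) − T(up)) ÷ cycle × 100 |
| L/R Stance % | 100 − swing % (exact complement) |
| DoubleSupport % | 100 − LeftSwing % − RightSwing % |
| L/R SwingSpeed | chord (ankle displacement up → down) ÷ swing time |

The cadence constant is 120 rather than 60 because a full gait cycle
contains one step of each foot; at a typical 0.96 s cycle this gives
125 steps/min, consistent with published adult gait tables, whereas 60
would give an implausible 62.  Swing speed is defined as the chord over the
swing duration; published summary tables for this quantity are not
reproducible from their own stride and swing-time medians under any
displacement convention we tried (chord at the medians gives ≈ 3.6 m/s
against a printed ≈ 2.55 m/s), so the chord definition — the literal
reading of "average speed during a swing" given straight-line landing
geometry — is used and the simulator's analytic truth follows the same
definition.

Step lengths are only taken between landings within a single run of
consecutive available cycles, so a step can never straddle a turnaround or
a discarded cycle.

## GPM details

Foot events inside turn intervals are removed, then the first and last
remaining foot events are dropped (gait is unstable at the ends of the
capture), and the rest are chunked left to right into chains of 4.  A chain
with an illegal transition is stored with availability *No* and scanning
resumes at the first offending event, losing at most one cycle per error
burst.  Short trailing chains are stored unavailable.  Every chain receives
the next integer key, so adjacency between surviving cycles remains
explicit; pair-based parameters use only available entries with consecutive
keys.  Note the GPM checks *order*, not count: an isolated duplicated event
can re-align subsequent chains into legal rotations, which is accepted —
the affected chains still describe physically consistent cycles.

## Classifiers

**SVM** — RBF kernel, `C = 1.0`, kernel width `gamma = 'scale'`
(1 / (n_features × variance)), one-vs-one multiclass, features standardized
with training-set statistics.  Sees single frames only.

**Bi-LSTM** — implemented in numpy in this package: one bidirectional layer
with 64 hidden units per direction over windows of `seq_len = 5` frames, a
per-slot 5-way softmax head, cross-entropy loss, Adam at 1e-3, 30 epochs,
batch 64, windows shuffled per epoch with a fixed seed.  Windows are
non-overlapping and never span walks; the tail window of each walk is
stored padded for layout but is *processed at its valid length*, so the pad
scalar never enters the recurrence — this makes predictions on real frames
provably independent of the pad value, and the training loss needs no
masking.  Gradients are verified against numerical differentiation in the
test suite.

Cross-validation assigns whole walks to folds (default k = 10): frame-level
splitting would leak temporal context between train and test.

## Heuristic baseline

The classical comparison method detects events from ankle speed alone:
the smoothed (5-frame moving average) 3-D ankle-speed magnitude is
thresholded at 0.25 × the per-segment peak; upward crossings are toe-offs,
downward crossings heel strikes.  Segment boundaries count as
below-threshold so a swing truncated by a boundary still registers.  The
original publications do not state their constants; both the fraction and
the window are config-exposed.  Turn detection is not attempted — turn
intervals are supplied externally (from labels) so the comparison isolates
event-localization quality.

## Synthetic data generator

The simulator emulates the capture protocol: standstill, then straight
passes of 5 m walked back and forth (default 6 passes = 3 round trips)
separated by in-place 180° turnarounds, at 30 Hz.  Within a pass a gait
cycle is laid out as left swing | double support | right swing | double
support, with configurable cycle time (default 0.96 s), swing fractions
(0.31/0.31) and step lengths (0.52/0.50 m) — values near the middle of
published adult ranges, and chosen so that every analytic parameter,
including the chord swing speed, falls inside the published min–max
envelope.  Stance feet are pinned to the ground; swing ankles advance one
stride with a half-cosine horizontal profile and half-sine lift, so the
chord equals the stride exactly and all 18 parameters have closed forms
(e.g. stride = step_L + step_R, speed = stride / cycle).  Passes start in
staggered stance so every swing covers a full stride.  The simulated
stance width is deliberately narrow (2 cm) so the Euclidean
landing-to-landing distance equals the configured step length to
sub-millimeter accuracy and the analytic truth is exact.

Cohorts draw per-walk gait parameters uniformly from adult ranges
(cycle 0.85–1.15 s, steps 0.45–0.60 m, swing fractions 0.27–0.35).
Position noise is i.i.d. isotropic Gaussian per joint per frame (benchmark
default 5 mm, the typical depth-camera jitter magnitude); labels always
come from the schedule, never from noisy positions.

What the generator does **not** model: arm/trunk dynamics, pathological
asymmetry or tremor, tracking dropouts, autocorrelated sensor noise,
realistic turning kinematics (turn frames are discarded downstream), or
ground-truth label noise.  Passing tests therefore demonstrate correctness
of the event logic, validation and parameter arithmetic, and the relative
robustness ordering of the methods under position noise — not clinical
accuracy on real recordings.

## Numerical choices and degenerate inputs

* Velocities use a causal backward difference with the first row copied;
  zero time steps fall back to the nominal 1/fps.
* Event localization is quantized to the 30 Hz frame grid.  A swing spans
  only ~7–9 frames, so one frame of timing is 11–14 % of a swing time; the
  recovery tests propagate this one-frame bound through each definition
  (e.g. swing speed inherits a frame of timing in the denominator plus the
  sub-frame ankle advance at the detected toe-off) rather than asserting a
  uniform percentage.
* Standardization floors near-constant feature columns to unit scale.
* Stance is reported as the exact complement of swing, so
  swing + stance = 100 holds identically.
* Event-matching in segmentation accuracy is greedy in temporal order per
  event type with an inclusive tolerance |j − j′| ≤ t (an exclusive
  interval would make t = 0 reject exact hits); each prediction matches at
  most one true event.  Parameter-error SD is the population SD.
* Degenerate inputs error loudly: empty sequences, single frames, single
  training classes, dictionaries with no available cycles, zero-truth
  parameters (excluded with a notice).
* A label stream that opens mid-turn (possible for predicted labels) closes
  the dangling turn interval from frame 1.

## Benchmark problem sizes

The method-comparison benchmark simulates 30 walks with 5 mm noise and runs
sequence-level 10-fold cross-validation for both classifiers; on one CPU
this completes in a few minutes.  These sizes give stable orderings while
keeping the Bi-LSTM training (10 folds × 30 epochs) inexpensive; they are
the package's default study conditions, configurable in `BenchmarkConfig`.

## Known limitations

* The Bi-LSTM is a minimal single-layer implementation without dropout,
  gradient clipping or learning-rate schedules; it is adequate for the
  32-feature task but not tuned for large vocabularies of gait styles.
* The heuristic baseline reconstructs the ankle-speed method from its
  description; its published constants are unknown.
* Walking speed averages per-pass speeds; if passes differ in length a
  total-path-over-total-time convention would differ slightly.
* Segmentation accuracy matches events per type; a global matching would
  differ when types are confused between nearby events.
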