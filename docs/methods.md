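# Methods

## Problem

A single inertial measurement unit (IMU) on the pelvis — 3-axis
accelerometer plus 3-axis gyroscope at 100 Hz — carries enough
information about whole-body gait dynamics to regress the six sagittal
lower-limb joint angles (bilateral hip, knee, ankle flexion/extension,
in degrees). The scientific question this package operationalizes is
not just whether that regression works, but how it *generalizes across
populations*: does a model trained on pooled data from young adults,
healthy older adults and pre-operative hip-osteoarthritis patients
(**cross-population training**) beat a model trained only on the test
subject's own population (**within-population training**)?

Because the clinical recordings behind this question are private, the
package ships a synthetic data generator that reproduces the study's
*structure* — population sizes, protocols, sensor channels, dropout
artifacts, heterogeneity ordering — and the full analysis pipeline is
developed and validated against that synthetic stand-in.

## Synthetic gait model

Each participant is a draw from a population profile:

- Gait phase φ(t) advances at 2π·(cadence/120)·speed rad/s (cadence in
  steps/min → stride frequency cadence/120 Hz) plus a Gaussian
  random-walk jitter per sample (`phase_jitter_sd`, radians).
- Joint angles are truncated Fourier series in φ with K = 3 harmonics:
  angle = mean + Σₖ aₖ·cos(kφ + ψₖ). Amplitudes split a participant's
  range of motion in fixed fractions (0.75/0.18/0.07 of half-ROM);
  template phases ψₖ are shared across participants (with jitter) so
  that models can transfer between subjects. The right leg is evaluated
  at φ + π with amplitudes attenuated by the participant's asymmetry
  coefficient in [0, 1].
- The six IMU channels are a participant-specific 6×4 linear mixture of
  [cos φ, sin φ, cos 2φ, sin 2φ] (amplitude scaled by the speed
  multiplier) plus Gaussian sensor noise. Units are nominal
  m/s²- and deg/s-scale with no physical calibration — the real
  device's units after onboard gravity removal are undocumented, so no
  calibration claim would be meaningful.

This abstraction is deliberate: angles are an exact function of the
phase harmonics present in the IMU stream, so the task is learnable by
construction and the end-to-end pipeline can be validated, while no
claim of biomechanical fidelity (ground-reaction forces, pendular
dynamics, magnetometer effects) is made. Consequences for
interpretation: a passing end-to-end test shows that the pipeline —
windowing, leakage-free standardization, training, ensembling, metrics,
statistics — extracts what is extractable; it does not show that the
network would reach any particular accuracy on real gait data.

Default profiles mirror the study populations: young n=17 (three
self-selected speed conditions, multipliers 0.8/1.0/1.2), older n=20
(three speeds), pre-operative n=14 (one speed, shorter bouts, reduced
ROM, high asymmetry). Between-participant heterogeneity is a single
multiplier on all between-participant standard deviations, ordered
older (2.0) > preop (1.5) > young (1.0): older adults are the most
heterogeneous walkers, pre-operative patients share a common slow
cautious pattern, young adults walk most alike. Sensor dropouts are
Poisson-arrival gap starts with geometric lengths (mean 3 frames), so
both the interpolation branch (≤ 5 frames) and the exclusion branch
(> 5 frames) of preprocessing occur; synchronization taps are sharp
transients added to the accelerometer near bout start and end.

All randomness flows from one integer seed; per-participant streams
are derived by seed offsetting, so a dataset is a pure function of
(profiles, seed).

## Preprocessing

Missing-sample runs of ≤ 5 frames (50 ms at 100 Hz) that are bounded by
valid data on both sides are filled by per-channel linear
interpolation; longer runs are excluded and split the recording into
separate segments. Runs touching the sequence edges are always
excluded, since linear interpolation needs two anchors — the protocol
source is silent on edge gaps, and this is the conservative choice.
Valid samples are never altered.

Tap detection finds the largest acceleration-magnitude excursion above
median + k·MAD (default k = 8) in the leading and trailing search
windows; the robust threshold tolerates the gait signal's own variance.
Synchronization aligns first taps (offset), corrects linear clock drift
by the ratio of inter-tap spans (two anchor points justify only a
linear model), and resamples the second stream onto the first's clock.
The synthetic pipeline stores IMU and angle streams pre-aligned, so the
main pipeline skips synchronization; it is exercised by tests that
artificially delay and drift-resample a stream.

## Windowing and standardization

A 200-sample (2 s) window slides with stride 10 (100 ms; 95% overlap)
within each valid segment, never across segment boundaries (continuity
across an excluded gap is undefined). The target is the angle vector at
the window's final frame, so estimation is causal. A segment of length
T yields max(0, ⌊(T − 200)/10⌋ + 1) windows; segments shorter than one
window simply yield none.

Z-score standardization is per channel (6 inputs over all frames, 6
targets over final frames), fitted on the training participants'
windows only, and refit for every inner-loop split — the strictest
reading of train-only statistics. Predictions are mapped back to
degrees before any metric is computed. Zero-variance channels are
rejected by name rather than silently producing NaNs.

## Network

A 1D residual CNN maps the standardized 6×200 window to 6 angles:
k7 conv (no bias) → BN → GELU → k3/s2 max pool; four stages of two
BasicBlocks (k3 convs without bias, BN after every conv, GELU at the
skip join; stride-2 first block and 1×1-conv + BN projection skip in
stages 2–4); global average pooling; head of three
Linear → GELU → Dropout(0.2) layers (256/128/64) and a linear output.
This configuration is the unique standard arrangement that reproduces
the published figures exactly: 4,019,014 trainable parameters
(15.33 MiB at 4 bytes each) and temporal lengths
200 → 100 → 100 → 50 → 25 → 13. Block-internal activations are GELU
(stem and head activations are named in the source description; block
activations are not — the parameter count is unaffected either way).
`width_multiplier` scales the convolutional widths for desk-scale work
and is not part of the reference architecture.

The network, its backpropagation, the Huber loss and the Adam optimizer
are implemented directly in NumPy (float32, im2col convolutions); the
engine is seeded end to end, so initialization, dropout masks and
sampling order are reproducible bit-for-bit on a fixed platform.
Analytic gradients are verified against central finite differences in
the test suite.

## Training protocol

Participants are assigned once, per group, to five balanced folds
(sizes differ by at most one); the assignment is persisted and reused
by both strategies. Nested cross-validation: outer loop over test
folds; inner loop rotates the remaining four folds through one
validation and three training folds, giving four models per outer fold.
Within-population runs restrict all splits to one group; cross-
population runs pool the matching fold numbers of all groups, so test
participants are never seen in training under either strategy
(audited by test).

Reference hyperparameters: Adam (lr 0.001, default moment
coefficients), Huber loss on standardized targets (δ = 1.0 — the
threshold is not documented at source, so the conventional unit
threshold on z-scored targets is used and is configurable), 100 epochs,
batch 128, no early stopping or schedule; the final-epoch model is
used and validation loss is monitoring only. Participant imbalance is
offset by weighted random sampling with replacement: window weight
1/n_windows(participant), draw count per epoch equal to the number of
training windows, applied to training data only.

Test predictions are the arithmetic mean of the four inner-fold models'
outputs, each de-standardized with its own statistics; per-model
predictions are retained so the alternative summary (average of
per-model metrics) remains computable.

## Metrics, aggregation, statistics

Per participant and joint side: MAE (degrees) and Pearson R over the
final-frame values of all test windows — one point per window, matching
the target definition (whether the source pooled per window or per
resampled trajectory is unstated; this reading is the direct one).
Bilateral joint values are means of left and right; the participant
average is the mean of the six joint-sides. Undefined R (constant
channel) propagates as missing, not zero. Boxplot summaries use
linear-interpolation quartiles and 1.5×IQR fences (outlier counts
depend on the quartile rule, hence it is pinned).

ΔMAE = MAE_cross − MAE_within (negative = improvement) and
ΔR = R_cross − R_within (positive = improvement), per participant and
group. Per group and metric: two-sided Wilcoxon signed-rank test with
zeros excluded, average ranks for ties, tie-corrected variance and a
half-rank continuity correction on the normal deviate — the correction
keeps the approximation within ~0.02 of the exact enumeration down to
n = 10, and the exact p is computed alongside for n ≤ 12. The 95% CI of
the mean Δ is a percentile bootstrap over participants (the
exchangeable unit), 10,000 resamples by default. Bonferroni correction
spans the 6 tests (3 groups × 2 metrics). Effect size r = |z|/√n with n
the informative pairs, signed by the median paired difference (the
rendering r = z/n in the source is inconsistent with its own reported
magnitudes, e.g. |z| ≈ 2.81 at n = 20 giving 0.63, which is z/√n).

## Desk-scale study

The full protocol (52 participants, 10-minute bouts, 100 epochs,
full-width network) is far beyond a single-CPU test budget, so the
shipped end-to-end study is a scaled replica whose sizes are the
package's own choice: three populations of 5 participants, single-speed
bouts of 45–60 s (30–40 s for preop), sensor noise 0.01,
quarter-width network, 5 epochs, windows capped at 2,000 per
participant, one outer test fold, three seeds with majority voting.
Under these conditions the within-young ensemble reaches test MAE
< 5° with mean R > 0.9, and on the high-heterogeneity older population
cross-population pooling does not increase the ensemble error
(mean ΔMAE ≤ 0) — the qualitative signature of the full study. A ridge
regression from flattened windows is reported alongside as a linear
baseline; at desk scale the network typically beats it, but a 5-epoch
run carries no guarantee against a closed-form fit, so the comparison
is diagnostic rather than asserted.

## Numerical choices and edge cases

- float32 throughout the network; metrics and statistics in float64.
- BN eps 1e-5, momentum 0.1; Adam eps 1e-8, β = (0.9, 0.999).
- Conv init: He-normal (fan-in); linear init: Kaiming-uniform with
  bias bound 1/√fan_in.
- Tie-breaks: representative selection resolves distance ties by
  lowest participant id; max-pool gradient follows the per-window
  argmax (first occurrence on exact ties).
- Degenerate inputs: empty bout plans, zero-variance channels,
  all-zero paired differences, missing taps, and tampered pipeline
  artifacts all raise typed errors rather than propagating silently.

## Known limitations

- The IMU model is a harmonic mixture, not rigid-body physics; transfer
  results quantify pipeline behaviour, not clinical accuracy.
- Group-level results of the original study depend on its private
  recordings and are not reproduction targets here; only its printed
  architectural facts and arithmetic are.
- The NumPy engine is CPU-only and single-threaded in BLAS-bound
  sections; the full-scale protocol is supported but slow, and the
  desk-scale profile is the intended test path.
- Angle targets are noise-free by construction; real motion-capture
  references carry their own error, which the synthetic study does not
  model.
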