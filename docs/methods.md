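# Methods

## Signal model and windowing

Input recordings are monocular gaze streams at a nominal 1000 Hz from a
jumping-point task: a target dot shown at 100 successive positions for 1 s
each, gaze and target in degrees of visual angle (DVA). Pixel coordinates
are converted per axis as `angle = arctan(offset_mm / viewing_distance)`
from the screen centre; arctan (rather than the small-angle linear map)
stays exact at large eccentricities, and the two conventions agree to well
under 0.1° inside the central 10°.

Each retained stimulus position contributes one window of 303 samples
starting at stimulus onset, covering the latency → saccade → fixation
sequence. 303 is the minimal length for which three point-to-point
differences leave 300 samples, i.e. exactly three 100-sample segments. The
velocity (302), acceleration (301) and jerk (300) series are aligned on
their **trailing** 300 elements so that every channel covers the same raw
samples (window indices 3..302); trailing alignment keeps all channels
co-registered with jerk, whose support is the binding constraint.

Positions are rejected whenever any sample of their full 1000 ms dwell
block is NaN; invalid samples are the sole rejection trigger, and a
non-zero tracker validity flag is normalised to NaN on read so the two
conventions cannot disagree. A common position set is enforced across all
trials of an experiment (the first *X* positions, in stimulus order, of the
cross-trial intersection of clean positions), so every subject and session
contributes the same stimulus indices.

## Features

Per segment, seven 100-element channels: `v`, `a`, `j`; their fractional
point-to-point changes `vc`, `ac`, `jc`; and the amplitude spectrum `Ft` of
the segment's velocity. Choices that the formulas leave open:

- **Δt convention.** Derivatives divide by the 1 ms sampling interval in
  seconds (units °/s, °/s², °/s³). Any constant factor is absorbed by
  min-max scaling, so this is cosmetic but documented.
- **Percentage-change guard.** `vc[i] = (v[i+1] − v[i]) / v[i]` is kept as
  a fraction; denominators with |v| < 1e−12 yield 0, because fixation
  velocity hovers at ~0 and unguarded division produces unbounded values
  that would dominate the scaled channel.
- **Percentage-change length.** A fractional change over a 100-sample
  segment yields 99 values; the channel is right-padded by repeating its
  final value so all channels are uniformly 100 elements.
- **Spectrum.** `Ft` uses all 100 DFT bins of the *unscaled* segment
  velocity (the conjugate-symmetric upper half is retained rather than a
  one-sided spectrum); the channel is min-max scaled afterwards like every
  other.
- **Scaler fitting.** Per-channel (lo, hi) bounds are fitted on the
  training sessions of each fold only and applied to the held-out session
  with clipping to [0, 1]; fitting on the union would leak test statistics
  into the transform. A degenerate channel (hi == lo) maps to zeros.
- **Statistics.** The 16-vector is (min, max, mean, std) of `v`, `a`, `j`,
  `Ft` in that fixed channel-major order, computed from the scaled
  channels; std is the population form (divide by N).

## Classifiers

Two fixed architectures:

- **LSTM:** recurrent(64, returns sequences) → dropout(0.5) →
  recurrent(64, final state) → dense(64, relu) → softmax(*l*); input is the
  100-step × 7-channel segment matrix. Dropout sits only between the two
  recurrent layers. Forget-gate biases initialise to 1, input kernels
  Glorot-uniform, recurrent kernels orthogonal.
- **Dense:** 16 → 100 → 75 → 50 → softmax(*l*) with relu hidden units.

Both use Adam (lr 0.001, β₁ 0.9, β₂ 0.999, ε 1e−7) on categorical
cross-entropy, minibatch size 64 (configurable; the batch size is not a
modelled quantity), and train for a fixed epoch budget with early stopping
disabled so folds remain comparable. The networks are implemented directly
in numpy (float32 parameters; buffers follow the parameter dtype), with
forward/backward passes verified against central-difference gradients in
the test suite. Training is single-threaded and deterministic given the
seed; bit-exactness across BLAS builds is not promised.

## Evaluation protocol

Leave-One-Session-Out: *S* folds, fold *i* holding out all samples of
session *i*. Within a fold each segment sample is classified independently;
the X·G probability vectors of one user are averaged and the identity is
the argmax of the fused vector (ties, a measure-zero event, resolve to the
lowest class index). Accuracy, macro-averaged F1 and Cohen's kappa are
computed on the fused per-user decisions (one decision per user per fold);
`per_sample_metrics=True` exposes the pre-fusion diagnostics. Fold metrics
are aggregated as arithmetic mean and population standard deviation.
Macro-F1 is used because the label sets are balanced by construction and
macro is the standard multiclass companion to kappa.

## Synthetic data generator

The simulator emulates the study conditions rather than a detailed
oculomotor plant. Event structure per stimulus jump: hold the previous
fixation for a latency ~ N(latency_mean, latency_sd) clipped to
[80, 400] ms (defaults 170 ± 15 ms, within the physiological 150–200 ms
band); execute a minimum-jerk saccade toward the target with proportional
undershoot; then fixate with a slow drift (random direction, default
0.3 °/s) plus white Gaussian noise (default 0.05° SD).

Saccade kinematics follow a saturating main sequence
`v_peak(A) = vpeak_scale · (1 − e^{−A/5°})` with `vpeak_scale` defaulting
to 520 °/s, giving ≈ 290–510 °/s over the task's 4–20° jumps, and duration
`D = 1.875·A / v_peak` (the minimum-jerk identity), ≈ 26–74 ms. The
`duration_slope` parameter (ms/°, default 0) lengthens saccades additively
per degree for subjects whose saccades are slower than their peak-velocity
scale implies. `vpeak_scale` is the primary identity knob; latency mean,
undershoot fraction and drift also differ across a generated cohort.
Session-to-session template aging is modelled as bounded perturbations:
multiplicative peak-velocity gain with |log gain| ≤ 0.2, a latency shift
≤ 50 ms and a noise inflation factor in [0.5, 2].

Blinks are injected per position as Poisson-count events replacing
50–150 ms runs with NaN, confined to their dwell block so contamination is
attributable to single positions.

The generator reproduces: event timing, main-sequence monotonicity,
per-subject separability, session drift and NaN structure. It does **not**
reproduce microsaccades, tremor spectra, oculomotor-plant dynamics,
tracker-specific noise colour, or the behavioural variability of real
participants — so passing identity-recovery tests demonstrates that the
pipeline extracts and classifies the signal it is pointed at, not that real
populations are separable at the published rates.

## Study sizes used in tests and the acceptance run

The identity-recovery study uses 8 subjects × 3 sessions × 20 positions
× 3 segments = 1440 samples, with adjacent subjects' `vpeak_scale`
separated by 25%, the LSTM trained 30 epochs and the dense model 50 — a
cohort small enough to iterate on while leaving fused LOSO accuracy far
above the 12.5% chance level (measured: ≈ 0.71 LSTM, ≈ 0.67 dense at
seed 1). Published-scale accuracies require the corresponding real
multi-year recordings and are outside what synthetic data can certify.

## Numerical notes and limitations

- Degenerate inputs: empty recordings, non-monotone timestamps, windows
  containing NaN, schedules/recordings of mismatched length, and designs
  whose sample counts disagree with the data all raise typed errors rather
  than propagating silently.
- `select_common_positions` reports the achievable count when the
  cross-trial intersection is too small.
- The first stimulus position of a simulated trial starts from gaze at the
  screen centre, so its first saccade amplitude is not drawn from the
  configured range; analyses that care should skip position 0.
- Fusion assumes every user contributes samples to the held-out session;
  absent users simply yield no decision for that fold.
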