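# Methods

`bcgbeat` detects heartbeat events (J-peaks) in ballistocardiograms (BCG) by
regression onto a *surrogate signal*: discrete reference heartbeats are
encoded as a continuous target, a sequence-to-sequence convolutional model
approximates that target from the 3-axis acceleration signal, and peak
detection on the approximation recovers the events. This note documents the
model, the synthetic study conditions, and the numerical and design choices
that are not obvious from the code.

## Problem and model

A BCG recording is `X ∈ R^{n×k}` (`k = 3` axes, equidistant samples at
`fs = 64 Hz`). Reference heartbeats are timestamps `P = {p}` from a
simultaneous ECG (R-peaks). Rather than classify samples, the detector
learns `M : X ↦ y`, where the surrogate `y ∈ R^n` encodes the events:

* **rectangular** — 1 within `|t − p| ≤ τ/2` (binary masking with an area of
  interest), 0 elsewhere;
* **triangular** — `max(0, 1 − 2|t − p|/τ)`;
* **quadratic** — `(1 − 2|t − p|/τ)²` inside the support. Written this way
  its peak slope is `4/τ`, twice the triangular slope at equal width — the
  alternative parabola `1 − (2(t−p)/τ)²` has zero slope at the peak and was
  rejected for that reason;
* **distance-time** — `min(clip, distance to nearest event)`, re-oriented to
  `(clip − y)/clip` before training so that one maximum-seeking decoding path
  serves all encodings.

Contributions of beats closer than `τ` are **summed** (superposition), not
clipped or maximised. Default widths: `τ = 0.8 s` (triangular and
rectangular) and `τ = 1.2 s` (quadratic); distance clip 1.0 s. Sample `i`
sits at `t0 + i/fs`; events are continuous-valued and never snapped to the
grid before encoding.

Decoding smooths the model output with a zero-phase second-order low-pass at
7.5 Hz and applies maximum-seeking peak detection with minimum spacing 20
samples (312.5 ms — max 192 bpm), height 0.01 and prominence 0.1 on the
surrogate's own scale. Zero-phase smoothing matters: a causal filter would
skew the approximation and bias every detected time late.

## Architectures and training

Both models map `(3, n)` to `(1, n)` with "same" zero padding.

* **CNN** — three convolutions of 64, 128 and 1 output channels with kernel
  widths 5, 65 and 129, ReLU between layers; 550 145 parameters.
* **ResNet** — an 8-channel stem (kernel 5), two strided residual blocks down
  (8→16→32, stride 2) and two transposed-convolution blocks up (32→16→8),
  batch normalization inside blocks and 40 % dropout between them, then a
  single-channel kernel-5 projection. Residual internals (two convolutions
  per block, kernel 5, 1×1 projection skips, nearest-neighbour upsampling in
  the decoder skips) are package choices within those constraints. Input
  length must be divisible by 4.

Training minimizes mean-squared error (the canonical loss for a real-valued
target; no loss is otherwise implied by the method) with Adam at learning
rate 1e-4, batch 32, 40 epochs by default; the best-validation-epoch weights
are kept when a validation set is supplied. All randomness (initialization,
shuffling, dropout) derives from one integer seed, and training is exactly
reproducible.

Two numerical choices stabilise short training budgets:

* the **output convolution is zero-initialized** (hidden layers He). The
  untrained model then predicts the surrogate's zero baseline; otherwise
  initialization noise sits right at the fixed peak-detection thresholds and
  short runs waste their budget unlearning it;
* Adam uses a short **linear learning-rate warm-up** (default 10 steps).
  Early Adam updates are near-sign steps of size `lr` for every parameter;
  with ~16 k output weights moving coherently this can swing the output by
  tens of units in one step, permanently killing ReLUs at learning rates
  above ~1e-3. Warm-up removes the failure mode and is negligible for long
  runs. Aggressive-rate experiments (e.g. the single-window capacity check at
  lr 1e-3) use a 200-step warm-up.

The engine is pure numpy/scipy in float32. Convolutions with wide kernels
run in the frequency domain (circular correlation with zero padding; weight
gradients are evaluated only at the `k` kernel lags via a small inverse-DFT
matrix product); narrow or strided kernels use a BLAS tap-loop. Both paths
are cross-checked against each other and against numeric differentiation in
the test suite.

## Synchronization

R-peaks lead J-peaks by the RJ-interval (180–240 ms, drifting slowly), and
acquisition clocks may drift. Alignment works purely on events: the
synchronicity of two event series is the mean distance from each event to
its nearest counterpart (symmetrised by averaging both directions); the
delay estimate is the minimiser of that score over an exhaustive shift grid
(default ±2 s in steps of one sample period, 1/64 s) with parabolic
refinement. When *scoring* candidate shifts, distances are capped at 0.25 s
so missed or spurious beats cannot dominate the search; the *reported*
nearest-event metric (`NAd_sym`) is never capped. Non-linear alignment
estimates one delay per 300-s segment, interpolates piecewise-linearly
between segment centres (segments with under 5 events inherit interpolated
values), applies the time-varying correction, and enforces monotonicity.
Segment length and the interpolation model are package choices; exhaustive
grid search replaces the published sparse-evaluation algorithm deliberately —
correctness over speed at desk scale.

A caveat inherent to event matching: a *perfectly periodic* beat train is
ambiguous modulo its period, so alignment relies on physiological beat-to-
beat variability (always present in the generator and in real data).

## Preprocessing and window quality control

Recordings acquired above 64 Hz are cubic-spline resampled to 64 Hz. The
working band is a zero-phase 4–25 Hz Butterworth bandpass (4th order,
forward–backward; zero phase because event *times* are the target).
Windows are 64 s (4096 samples); each window is normalized per channel by
`(x − median)/IQR`, computed within the window — robust to movement bursts,
and matching the windowed training regime (the recording-level alternative
would leak night-scale statistics into windows). A flat channel (zero IQR)
is scaled by 1 and flagged rather than crashing.

Training windows pass a synchronization QC: preliminary J-peaks from the
classical detector are compared with the (already aligned) reference events
per window over ±2 s; windows with residual delay ≥ 0.1 s — or too few
events, or no stable detector lock — are excluded from training. Validation
windows are never filtered: the detector must be evaluated on everything.

At night scale, inference uses half-overlapping windows with seam
de-duplication (two detections within the minimum spacing merge, keeping the
higher peak): a beat on a window edge cannot be a local maximum of that
window but is interior to its neighbour.

## Classical baseline

The comparison detector is a Pan-Tompkins-style chain: 1.5–22.5 Hz bandpass
(the recommended BCG system bandwidth), pointwise cube (odd power — sharpens
peaks without flipping polarity), 10 Hz low-pass, second-order derivative,
absolute value, 5 Hz low-pass, then peak picking with a 0.31 s refractory
spacing and an adaptive height threshold of 0.3 × the 95th percentile of the
processed signal computed in 8-s blocks. The two low-pass cutoffs, the
threshold rule and the block length are package defaults fixed once on
synthetic data (the source pipeline's constants are not published); the
8-s threshold block keeps the detector functional through movement bursts
instead of silencing a whole minute. It operates on the dominant-variance
axis by default (`channel="norm"` combines all three).

## Synthetic sleepers

The generator replaces a private dataset and emulates only the statistics
the pipeline depends on:

| parameter | default | meaning |
|---|---|---|
| `mean_ibi` | 0.92 s (drawn 0.82–1.02 across subjects) | mean interbeat interval |
| `ibi_sd` | 0.03 s | beat-to-beat Gaussian jitter |
| `rsa_freq`, `rsa_depth` | 0.25 Hz, 0.02 s | respiratory sinus arrhythmia |
| `rj_base`, `rj_drift_amp`, `rj_drift_period` | 0.21 s, 25 ms, 600 s | slowly drifting RJ-interval, kept inside 0.18–0.24 s |
| IJK template | 5 Hz Gabor-like damped cosine, 0.15 s decay | global maximum defines the J-peak; side lobes play the I and K waves |
| channel weights | (0.2, 0.3, 1.0) | one dominant axis, as for a chest-aligned IMU |
| `resp_amp`, `resp_freq` | 0.5 units, 0.25 Hz | respiration baseline |
| `noise_sd` | 0.35 units | broadband sensor noise |
| `movement_rate` | 6 / h | Poisson bursts of 2–10 s at 10× noise amplitude |
| `clock_drift_ppm` | 0 | optional linear clock drift of the signal axis |

IBIs are `mean_ibi + RSA + jitter`, clipped to 0.33–2.0 s, accumulated from
zero. The noise default was calibrated once so that the classical baseline
is imperfect but functional (beat recall ≈ 0.8–0.9 at 100 ms) — giving the
learned detector real headroom without making the task artificial — and was
not revisited afterwards.

What the generator does **not** emulate: real IMU transfer functions, bed
mechanics, posture changes, waveform non-stationarity within a night, or ECG
morphology (only R-peak times are used). Passing tests therefore demonstrate
the pipeline's correctness and its behaviour under controlled degradations,
not clinical performance.

## Evaluation

Four complementary metrics compare detected J-peaks with reference R-peaks:

* **HR MAE** (bpm) — heart rate per 64-s window as `60 / mean(IBI)`; MAE over
  windows. Reported in bpm throughout (the source material is inconsistent
  between seconds and bpm for this quantity; its agreement plots use bpm).
* **HR MAE 8 s** (bpm) — the same over non-overlapping 8-s tiles of each
  window. Sub-windows with fewer than two events on either side are excluded
  and counted, not imputed.
* **NAd_sym** (ms) — symmetric mean nearest-event distance after removing the
  optimal global delay; uncapped.
* **IBI MAE** (ms) — both series are converted to interbeat-interval step
  functions (each IBI attributed to the interval it terminates), sampled on
  a common 1 Hz grid over their overlap after global delay removal. The
  step-function comparison pairs sequences of different lengths gracefully:
  one missed beat inflates the error only inside the doubled interval.

Bland–Altman agreement uses per-8-s-window residuals `hr_ref − hr_est` with
limits `bias ± 1.96·sd` (sample sd). Cross-validation is grouped by subject
(leave-subjects-out; leave-one-subject-out when folds equal subjects):
training folds are QC-filtered, validation folds are not, and aggregates are
mean ± sd **across subjects**. An ungrouped mode (single split with every
subject on both sides) exists for intra-subject analyses and warns when
used. The grid search runs a grouped CV per kernel configuration (optionally
at reduced epochs) and ranks by 64-s HR MAE, emitting the full table.

## Problem sizes

The package's reference study — run by `scripts/acceptance.py` and the
end-to-end tests — uses 4 subjects × 20 min at 64 Hz, CNN + triangular
kernel trained 10 epochs with leave-one-subject-out validation. At this
scale non-overlapping training windows give only ~2 gradient batches per
epoch, so the pipeline defaults to a 16-s training stride (overlapping
windows; evaluation tiling stays non-overlapping at 64 s). Night-long
datasets make the overlap unnecessary. The single-window capacity check
uses a 16-s crop (1024 samples), lr 1e-3, 200-step warm-up, 600 steps.

## Known limitations

* The generator's linear superposition of template, respiration and noise is
  far cleaner than real BCG; absolute metric values on synthetic data are
  optimistic and only relative comparisons (learned vs. classical, kernel A
  vs. kernel B) transfer qualitatively.
* The event-matching estimator cannot disambiguate a strictly periodic train
  (alias locking); it depends on natural heart-rate variability.
* Very high heart rates (> 192 bpm) are invisible to the default peak
  spacing, and rates below 30 bpm exceed the IBI clip of the generator.
* The numpy training engine is single-threaded CPU code; it is sized for the
  desk-scale studies above, not for training on many full nights.
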