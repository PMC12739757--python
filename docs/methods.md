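# Methods

`xmodal-affect` implements a multimodal emotion-recognition pipeline for
physiological recordings: EEG and peripheral-signal feature sequences are
encoded by two identical convolutional branches and fused by bidirectional
multi-head cross attention before classification. Because the public
affective datasets this kind of model is usually evaluated on are
registration-gated, the package ships a synthetic-data generator that
reproduces the statistical structure the pipeline assumes, so every stage —
and the full training loop — is testable from a cold start.

## Synthetic recordings

Each trial is a pure function of `(SimulationConfig, subject, trial_index)`:
a root seed is split hierarchically per (subject, trial) cell
(`numpy.random.SeedSequence` spawn keys), so generation is reproducible
bit-for-bit and order-independent.

- **EEG** (default 8 channels at 128 Hz): 1/f-amplitude ("pink") Gaussian
  background, shaped in the frequency domain above a 0.5 Hz shoulder and
  normalized to `noise_sd` per channel. Pink noise matches broadband EEG
  spectra far better than white noise, which matters here because the
  features are band-power based. During the stimulus period (not the
  baseline), the trial's class adds a sinusoid with random in-band frequency
  and random phase on the first 25 % of channels (at least one). Class 0
  boosts alpha (8–13 Hz), class 1 beta (13–30 Hz), class 2 theta, class 3
  gamma. The amplitude is `0.5 * effect_size * noise_sd`, so designated-band
  power grows monotonically with `effect_size` and `effect_size = 0` removes
  all class structure.
- **Peripheral channels** (default 4 at 128 Hz): slow sinusoidal drift
  (0.05–0.2 Hz) plus white noise whose gain and mean shift with the class
  fraction `label / (n_classes − 1)` — emulating arousal-coupled amplitude
  changes in signals like skin conductance.
- **Eye movements**: fixations, saccades and blinks are homogeneous Poisson
  event streams whose rates scale with class (base rates 2.0, 1.8 and
  0.25 /s — typical free-viewing values); durations are lognormal
  (fixations ≈ 250 ms, blinks ≈ 150 ms), saccade amplitudes gamma
  (shape 2, scale 2°). The pupil-diameter trace (50 Hz, X and Y) is a 4 mm
  baseline with a slow oscillation and Gaussian noise whose SD grows with
  class, so pupil variability is class-informative.
- **Trial layout**: a `baseline_seconds` pre-stimulus segment (default 3 s)
  carrying no class signal is prepended to the 60 s stimulus period, the
  layout used by stimulus-locked affective experiments.

What the generator deliberately does **not** emulate: scalp topography and
volume conduction, inter-channel correlation structure, artifacts
(ocular/muscular), non-stationarity within a trial, and realistic label
noise. Passing tests therefore demonstrate that the pipeline recovers
class-conditional band-power and variance structure — not that it would
reach any particular accuracy on real recordings.

## Preprocessing

All filtering is 4th-order Butterworth applied forward–backward
(`sosfiltfilt`), i.e. zero-phase, so filtered signals stay temporally
aligned across modalities; the effective power response is the square of
the one-pass response. Resampling is polyphase anti-aliased decimation
(upsampling is rejected). Band sets: theta/alpha/beta/gamma
(4–8/8–13/13–30/30–45 Hz) for 128 Hz recordings with a 4–45 Hz broadband
pre-filter, and delta through gamma (1–4/4–8/8–14/14–31/31–50 Hz) for
200 Hz recordings. Windowing floors the window count (a trailing partial
window is discarded): 60 s at 4 s windows gives exactly 15 windows.

## Features

**Differential entropy.** For a Gaussian signal, DE = ½ ln(2πeσ²) nats. The
estimator uses the sample variance (ddof = 1), floored at ε = 1e−10 so a
constant window yields a large negative but finite value rather than −∞.

**Band DE.** Each 4 s window is Hann-tapered; the one-sided periodogram PSD
is integrated over (low, high] and the Gaussian closed form applied to that
band variance. The integral (not the mean) of the PSD is used because it
equals the variance of the band-limited component (Parseval), which makes
band DE agree with the time-domain DE of the band-passed signal and makes
contiguous bands partition the total signal power. EEG features are ordered
channel-major then band, giving 62 × 5 = 310 dimensions for a 62-channel,
five-band setting and 32 × 4 = 128 for a 32-channel, four-band one.

**Peripheral statistics.** Per channel and window: mean, variance, and DE
(the same Gaussian estimator — the package's single entropy definition),
so 8 channels give 24 dimensions. Peripheral features are computed per 4 s
window rather than once per trial so both branches receive equal-length
sequences, which the cross-attention stage requires.

**Eye features.** A canonical 31-entry vector: pupil X/Y mean, SD and DE in
four sub-Hz bands (0–0.2, 0.2–0.4, 0.4–0.6, 0.6–1 Hz) — 12 values;
fixation-dispersion X/Y mean and SD — 4; fixation-, blink- and
saccade-duration and saccade-amplitude means and SDs — 8; and 7 event
statistics (blink/fixation/saccade frequency, fixation-duration maximum,
fixation-dispersion total and maximum using the per-fixation dispersion
magnitude √(dx²+dy²), and mean saccade latency). Empty event lists yield
zero frequencies and zero duration statistics (logged). Because the eye
vector is one value per trial while the peripheral branch consumes a
sequence, the vector is tiled across windows and concatenated to the
windowed peripheral statistics; this is a design choice of this package.

## Model

Both branches share one architecture: three cascaded blocks of
same-padded 1-D convolution over the window axis → ReLU → non-overlapping
max-pool → batch normalization (per channel over batch and time) → dropout.
Defaults: filters (64, 128, 128), kernel 3, pool 2, dropout 0.3. With 15
input windows the temporal length falls 15 → 7 → 3 → 1.

Fusion is bidirectional cross attention: `Attention_EEG` uses the
peripheral sequence as queries against EEG keys/values, `Attention_PERI`
the reverse; each is multi-head scaled dot-product attention (default 4
heads, model dimension 64) with per-head learned projections and an output
projection, and the two outputs are concatenated along the feature axis —
concatenation preserves both streams losslessly, and is this package's
reading of an otherwise open fusion choice. A temporal mean-pool, one
hidden layer (64 units, ReLU) and a softmax head produce class
probabilities.

The network is implemented directly on NumPy arrays with hand-derived
backward passes for every stage (convolution, max-pool argmax routing,
batch-norm, dropout, attention softmax, classifier), which keeps the whole
computation in float64 and allows the analytic gradient of the full loss
to be verified against central differences (agreement ~1e−10 relative on a
tiny model; the test bound is 1e−4). Weight initialization is a seeded
uniform fan-in scheme; biases start at zero, batch-norm at identity.

## Training and evaluation

The loss is mean cross-entropy plus `l2_lambda · Σw²` over weight matrices
(biases and batch-norm parameters excluded), minimized by Adam
(β₁ = 0.9, β₂ = 0.999) at learning rate 0.001 with batch size 64; the L2
coefficient defaults to 1e−4 (the protocol names L2 but not its value).
Evaluation is stratified five-fold cross-validation pooled across
subjects: per fold, features are z-scored with training-fold statistics
(input scaling is unspecified upstream; fold-local standardization avoids
leakage), and the model is re-initialized from a fold-specific seed so no
state crosses folds. Accuracy is correct/total — (TP+TN)/(TP+TN+FP+FN) in
the binary case — and always equals the confusion-matrix trace over its
sum. Rating-scale labels (1–9) binarize at > 5 (scale midpoint, exposed as
a knob), and the four-quadrant task crosses the two binarized dimensions
in the order HAHV, HALV, LAHV, LALV.

Two negative controls are built in: training-label shuffling within each
fold (a leakage guard that must drive accuracy to chance) and an
`effect_size = 0` dataset (a generator guard with the same expectation).

## Problem sizes and numerical choices

The shipped study configuration — and the default `SimulationConfig` — is
2 subjects × 40 trials, 2 classes, effect size 3, 8 EEG + 4 peripheral
channels, 60 s trials with 3 s baselines, 4 s windows, 50 training epochs
per fold. At these sizes the full pipeline (simulation through five-fold
CV) runs in about half a minute on one CPU core; the monotone-recovery
property is checked on a reduced setting (48 s trials, 20 trials, 8
epochs, a narrower model) to keep the suite quick. Degenerate inputs are
handled explicitly: constant channels hit the variance floor, empty event
lists produce zeros, attention on length-1 sequences reduces to the single
value row, and a sequence too short for a conv block raises an error
naming the block. Ties in max-pooling route the gradient to the first
argmax; probabilities are clamped at 1e−12 before logs.

## Known limitations

- The synthetic generator's class signal is a single sinusoid per trial;
  real affective EEG modulations are broadband, non-stationary and far
  weaker, so absolute accuracies here say nothing about real-data
  performance.
- Cross-validation pools windows' trials across subjects
  (subject-dependent evaluation); subject-independent transfer is out of
  scope.
- Artifact removal (ICA, EOG regression) is not implemented; real raw data
  are assumed to arrive cleaned through the adapter contract
  (`MultimodalRecording`).
- The NumPy implementation is single-threaded BLAS-bound; it is sized for
  the feature-sequence scale (tens of windows), not raw-signal-scale
  sequence modeling.
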