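# Methods

`rtseiz` implements a two-stage framework for pediatric scalp EEG: Stage 1
streams a binary seizure detector over sliding windows in real time; Stage 2
classifies each detected event into one of five ILAE-aligned categories —
normal, childhood absence epilepsy (CAE), infantile epileptic spasms
syndrome (IESS), other generalized epilepsy (GN) and focal epilepsy (FC).
Because the clinical recordings such a system is built for are not publicly
distributable, the package ships a synthetic-cohort generator and every
guarantee in the test suite is stated against that generator. This note
records the model, the preprocessing contract, the generator's scope, and
the design decisions that were genuinely open.

## Preprocessing contract

EDF recordings are read through MNE; channel labels are canonicalized
(strip `EEG ` prefixes and `-Ref`/`-LE` suffixes, lowercase) and the modern
t7/t8/p7/p8 names map onto the classical t3/t4/t5/t6 only when the
classical name is absent — both present is an ambiguity error.

1. **Montage.** The 22-pair longitudinal-bipolar ("double banana") montage
   with transverse pairs, in fixed clinical order ending `fz-cz`, `cz-pz`.
   Each pair row is the sample-wise difference of its two electrodes.
2. **Resampling.** Polyphase resampling to the 200 Hz common rate with a
   zero-phase anti-alias filter (chosen for determinism and the absence of
   edge transients beyond the filter half-width). Upsampling is out of
   scope. No band-pass or notch filtering is applied anywhere: the montaged,
   resampled, normalized signal is the model input.
3. **Normalization.** Min–max scaling `x → (x − min)/(max − min)` with
   statistics computed from training-fold recordings only. Granularity is
   per montage pair (channel amplitude scales differ systematically); a
   global scalar mode is available. Constant channels map to zeros rather
   than erroring (synthetic fixtures may contain flat channels), and test
   values outside the training range are *not* clipped, preserving their
   rank information.

## Windowing

Stage 1 consumes non-overlapping 30 s chunks tiled from "context" segments
— each seizure bracketed by up to one hour of surrounding signal, with
overlapping brackets merged — anchored at the segment start (the simplest
consistent tiling); trailing remainders under 30 s are dropped. Chunks
carry per-second labels; sliding windows (4 s or 12 s, 1 s shift; 27 and 19
per chunk respectively) are labeled by **any-overlap** with ictal seconds.
The any-overlap rule is a deliberate sensitivity-first choice — missing a
seizure is clinically worse than a false alarm — and a minimum-overlap
fraction is configurable. Training streams are rebalanced by keeping at
most ten non-seizure chunks per seizure chunk (sampled without replacement,
seeded); the rebalancing is applied to the pooled training stream so that
seizure-free control recordings still contribute all-negative chunks, and
evaluation always uses the full, unsampled stream so metrics reflect the
true imbalance.

Stage 2 consumes one clip per seizure: up to 30 s pre-ictal (truncated at
the previous seizure's offset or the recording start), the first 120 s of
the event, and up to 5 s post-ictal. Control patients contribute randomly
placed fixed-length clips (default three 60 s clips per patient, uniform
placement, seeded) labeled `normal`.

## Models

All models run on a small reverse-mode autodiff engine over numpy
(`rtseiz._nn`) written for this package: conv2d (strided/dilated),
depthwise conv, squeeze-excitation, LSTM, channel (instance) normalization,
Adam, and the two losses. Arrays are float64; forward passes are
deterministic on one thread, which the streaming-consistency contract
(stream vs batch ≤ 1e-6) relies on. Every layer's backward pass is verified
against central-difference gradients in the unit tests.

**Input layout.** Montage channels form the 2-D convolution's height axis:
a raw window is a 1×22×T image; a frequency-band window is a 7×22×frames
image (bands as conv channels). Temporal strides are input-aware: raw
signal at 200 samples/s is downsampled aggressively by the stems (stride
4), band frames (2 per second by default) are not.

**Detectors** (sigmoid output; the LSTM state persists across the 1 s-shift
windows of a chunk and resets at chunk boundaries — persistence is what
makes the recurrent head meaningful in streaming):

* `cnn2d_lstm` — three 2-D convolutions (3×5 kernels, stride 2×2).
* `resnet_short_lstm` — a full-height 22×7 stem collapsing the electrode
  axis, then 4 residual blocks of (1,5) temporal convolutions with channel
  norm.
* `resnet_short_dilation_lstm` — the same stack with temporal dilations
  1/2/4/8.
* `mobilenetv3_short_lstm` — a reduced inverted-residual stack
  (expand → depthwise → squeeze-excite → project, hard-swish) with a final
  pointwise convolution before pooling.

The exact layer counts of the reduced ("-short") stacks are this package's
own documented presets; `width_multiplier` scales all convolutional widths
(0.25 is the desk-scale setting used throughout the tests), and
`recurrent_hidden` sizes the LSTM.

**Classifiers** (5-way softmax; variable clip lengths are handled by global
temporal pooling, so a 35 s and a 155 s clip both yield fixed-size logits):
a stem of one-dimensional temporal filters applied per montage channel
followed by a full-height electrode-mixing convolution, then

* `cnn2d_lstm_clf` — conv stack, temporal pooling to ≤ 40 frames, LSTM;
* `resnet50_conv` — bottleneck residual stages 3/4/6/3 (expansion 4);
* `mobilenetv3_clf` — four inverted-residual blocks;
* `densenet_clf` — two densely connected blocks with a transition layer.

Three numerical choices matter for trainability at desk scale and are worth
recording. (1) Classifier bodies pool with concatenated global mean *and*
max over time: a ~9 s discharge inside a 44 s clip vanishes under mean
pooling alone. (2) The bottleneck stack uses zero-initialized residual
branch gains, so the 16-block network starts as a near-identity and its
gradients stay well-conditioned. (3) Instance normalization over a single
remaining time point would zero the signal; it degrades to a pure affine
map in that case, and classifier inputs are channel-standardized per clip
(band magnitudes are heavy-tailed and all-positive, which otherwise kills
early ReLUs). Output heads use small-scale (0.01×) initialization so
training starts near the prior.

## Training and evaluation

Adam, batch size 16 counted in model inputs (a detector's input is one
sliding window, so one 27-window chunk saturates a batch and yields one
optimizer step; classifier batches count clips — desk-scale runs use batch
1 to get enough optimizer steps out of tens of clips), up to 20 epochs, a
learning-rate sweep over {1e-3, 1e-4, 1e-5} with one candidate per rate
selected by validation loss on a held-out slice of the training stream.
Binary cross-entropy for detection, cross-entropy for classification; both
from logits, numerically stable. Global gradient-norm clipping at 5.0.
Scaled-down runs in the tests fix a single rate (1e-3) and fewer epochs
(5 for detection, 10 for classification); these are problem-size choices
documented here once.

Cross-validation is always patient-grouped — window-level splits would leak
near-identical signal between train and test — and group-stratified where
counts permit. Metrics: AUROC (rank probability, ties half), AUPRC
(step-wise precision–recall integration), and F1 at threshold 0.5 with a
clearly-labeled best-over-thresholds secondary value. Detection reports an
"Any" row over all test windows plus per-type rows whose negatives come
from the same type's patients and the normal controls (the subgroup
definition is a documented choice). Classification reports one-vs-rest
metrics per class and a support-weighted aggregate over the four seizure
classes (normal excluded by default, configurable). Single-class inputs
raise rather than returning NaN. Every aggregate is recomputable from the
persisted per-fold score dumps; the acceptance tests verify this
bit-identically.

## Synthetic cohort generator

The generator's purpose is pipeline testing with controllable difficulty,
not realism. Background EEG is spatially correlated 1/f noise (spectral
slope ≈ −1 over 2–40 Hz) at ~20 µV, with an amplitude-modulated ~9 Hz
posterior-dominant rhythm. Ictal events are additive parametric waveforms:

* **CAE** — ~3 Hz spike-and-slow-wave complexes on all electrodes;
* **IESS** — one high-amplitude slow wave (≤ 2 s, diamond envelope)
  followed by 1 s of 50 % diffuse attenuation (electrodecrement);
* **GN** — generalized polyspike-and-wave bursts at ~4.5 Hz (three ~25 Hz
  spikes per cycle);
* **FC** — an oscillation confined to a contiguous 6-electrode
  neighbourhood whose frequency evolves linearly 4 → 8 Hz.

Each event receives a random per-electrode amplitude topography (magnitude
0.55–1.0, random polarity): a spatially smooth profile would cancel almost
exactly in the bipolar montage, whose pairs subtract neighbouring
electrodes. The signal-to-background knob (default 4.0 × the 20 µV
background, i.e. ~80 µV peak) makes injected events recoverable by a plain
bandpower detector (≥ 95 % localized to within 1 s), which establishes that
the synthetic task is learnable before any model training. Event durations
are lognormal with per-type means following the study-scale cohort table
(CAE 9.2 s, IESS 0.95 s capped at 2 s, GN 7.95 s, FC 83.96 s); default
per-group patient counts mirror that cohort at roughly one tenth. Native
generation is at 256 Hz so the 200 Hz resampler is exercised on every
cohort, and EDF round trips are bounded by the 16-bit quantization step
(~0.25 µV over a ±8192 µV physical range).

**What the generator does not emulate — and what that implies.** The
background is stationary apart from the slow posterior-rhythm envelope:
there are no movement artifacts, electrode pops, EMG, eye blinks, or
arousal-state changes. Two consequences matter for interpreting test
results. First, passing the learnability checks here says the pipeline and
optimizers work, not that the models reach clinical performance on real
EEG. Second, the window-length trade-off *reverses*: on a stationary
background, the energy of a fixed ~1 s event is easier to detect in longer
windows (background energy variance shrinks with window length, and
any-overlap labeling gives 12 s windows proportionally more positive
labels), so the short-window advantage for brief spasm-like events that
motivates 4 s windows on clinical recordings does not reproduce on this
generator — the corresponding direction check in the acceptance suite
documents this as a failing test rather than hiding it. Reproducing the
clinical direction would require non-stationary background modeling, which
is outside the generator's scope.

## Two-stage chaining

The two stages are trained and evaluated separately; chaining them is this
package's extension in the direction the framework points. Stage-1
per-window probabilities are turned into candidate events by a
threshold-and-merge rule: a run of at least `m` consecutive windows
(successive start times exactly one shift apart; chunk boundaries break
runs) with probability ≥ θ becomes a candidate `[first window start, last
window start + window length]`, and overlapping candidates merge. Defaults
θ = 0.5, m = 3 (m suppresses isolated single-window false positives);
both are engineering choices exposed in configuration. Stage 2 then
classifies a clip built around each candidate with the same ≤30 s/≤120 s/
≤5 s bounds as training clips. Run bundles persist the per-window trace,
the candidate table and full provenance (config hash, seeds, library
versions), and every reported number is recomputable from those dumps.

## Known limitations

* The synthetic morphologies are labeled caricatures; the IESS
  electrodecrement in particular varies widely in reality, and no clinical
  claim follows from any result on generated cohorts.
* `cnn2d_lstm` trains reliably on separable toy streams but generalizes
  poorly on the hardest synthetic task (brief spasms) at desk scale.
* Event-level scoring (event sensitivity, false alarms per hour, latency)
  is not implemented; all detection metrics are window-level.
* EDF writing requires integer sampling rates and whole-second durations;
  EDF+ embedded annotations are not parsed (annotations travel in a CSV
  sidecar).
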