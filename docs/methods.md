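# Methods

## Problem setting

Wearable human-activity recognition (HAR) classifies short windows of a
continuous D-channel sensor stream into activity classes. Naturalistic
recordings are extremely imbalanced: the *Null* class (no activity of
interest) covers about 75 % of the data, and the sporadic gestures that
matter must be implicitly segmented as well as classified. The package
implements two classifiers for this setting and everything needed to
train and evaluate them end to end.

## Preprocessing

Raw recordings are whitespace-delimited numeric text (one row per time
step, channels + integer label column, `nan` for missing samples).
Three steps produce model input:

1. **Missing-value interpolation** — per channel, linear interpolation
   between the nearest observed neighbours; leading/trailing gaps take
   the nearest observed value (nearest-value extension avoids
   extrapolation artifacts at recording edges). A channel with no
   observations at all is an error.
2. **Normalisation to [0, 1]** — per-channel affine min–max map. The
   bounds are computed on the training split only and reused for
   validation/test (values outside them are clipped), so no information
   leaks from the evaluation data. A constant channel maps to zeros
   with a warning rather than an error.
3. **Sliding windows** — fixed length S1 with step `step_samples`,
   giving `floor((N − S1)/step) + 1` windows per recording; windows
   never span recording boundaries. Each window takes the label of its
   **last** sample: the class active at the moment the prediction is
   made, which is also the natural target for a recurrent model that
   outputs after seeing the whole window.

**Window length.** The defaults are S1 = 24 samples and step 12 at a
nominal 30 Hz. The canonical experimental setup for this architecture
family describes a 500 ms window with a 250 ms step, which at 30 Hz
would be 15 samples — too short to pass four valid length-5
convolutions (the feature map would vanish); the canonical layer sizes
(a flattened width of 64·113·8) imply a final map length of 8 and hence
S1 = 24. We therefore fix 24/12 as the implementable default.

## Architectures

Both models share a stack of `n_conv_layers` = 4 temporal convolutions
with `n_maps` = 64 kernels of length P = 5 per layer. Kernels are 1-D
in time, shared across all D sensor channels, with no cross-channel
mixing and no padding ("valid" convolution), so the channel axis is
preserved and the time axis shrinks by P − 1 per layer
(24 → 20 → 16 → 12 → 8). Activations are ReLU. There is no pooling.

* **DeepConvLSTM** (`C(64)×4 – R(128) – R(128) – Sm`): the final
  feature maps are read one time step at a time — the step-t input is
  the flattened F·D vector of all maps at time index t (map-major:
  element f·D + d is map f, channel d) — through two peephole-LSTM
  layers of 128 cells. Gates use the logistic sigmoid; the cell
  candidate and hidden readout use tanh; peepholes are element-wise
  vectors (the gates read the cell state); input and forget gates see
  c_{t−1}, the output gate sees the updated c_t. The initial state
  (h₀, c₀) is zero, not learned. The softmax readout is taken at the
  final time step only, once the whole window has been observed.
* **Baseline CNN** (`C(64)×4 – D(128) – D(128) – Sm`): the final
  feature-map tensor is flattened in C order (map, then channel, then
  time) into a 64·113·8 = 57,856-wide vector and passed through two
  128-unit ReLU dense layers and a softmax. The flattening order is a
  pure convention — changing it only permutes dense-weight rows.

Parameter accounting counts every trainable scalar. An LSTM layer with
n cells on an n_in-wide input has 4·n·n_in + 4·n² + 4n + 3n parameters
(four input matrices, four recurrent matrices, four biases, three
peephole vectors). For D = 113, S1 = 24 this gives layer sizes 384,
3 × 20,544, and 7,405,696 / 16,512 for the baseline's dense layers
versus 3,769,216 / 131,968 for the LSTM layers — the recurrent model
is ~7× smaller overall because it never flattens time into the dense
connection.

## Training

Mini-batch gradient descent on the mean cross-entropy of the
final-time-step prediction, with the RMSProp step-size rule

    cache ← ρ·cache + (1 − ρ)·g²,  θ ← θ − lr·g / √(cache + ε),

lr = 1e−3, ρ = 0.9, ε = 1e−6, cache initialised to zero, batches of
100 windows (last partial batch kept), one update per mini-batch.
Every 2-D weight matrix — conv kernels reshaped to 2-D, the four LSTM
input and four recurrent matrices separately, dense and softmax
matrices — is orthogonally initialised (QR of a Gaussian matrix with
the sign ambiguity fixed); biases and peephole vectors start at zero.
Inverted dropout with p = 0.5 multiplies the inputs of both hidden
layers and of the softmax layer during training (survivors scaled by
1/(1 − p), inference is mask-free). Early stopping monitors the
validation weighted F1 with a configurable patience, restoring the
best-epoch parameters. Given (seed, data, config) on one BLAS thread,
training is fully deterministic.

Gradients are computed by hand-written reverse-mode differentiation
(backpropagation through the conv stack and through time across both
peephole-LSTM layers). The contract is numerical: on small models of
both variants, central finite differences (step 1e−5, double
precision) agree with the analytic gradient to a relative error below
1e−4 on every sampled coordinate. Two numerical caveats are handled
explicitly in the checks: coordinates where two FD step sizes disagree
sit on a ReLU kink and are excluded, and the checks run at a randomly
perturbed parameter point because the zero-initialised biases can
place pre-activations exactly on the kink (where the loss is genuinely
non-differentiable yet symmetric differences look smooth).

The cross-entropy clamps the true-class probability at 1e−12 (logged)
so a saturated prediction cannot produce an infinite loss; a non-finite
loss aborts training with the history collected so far.

## Evaluation

The confusion matrix follows the rows = actual, columns = predicted
convention. Per-class precision TP/(TP+FP) and recall TP/(TP+FN)
combine into the sample-weighted F1, Σ_i 2·w_i·p_i·r_i/(p_i+r_i) with
w_i = n_i/N the actual class share. A class with an empty row or
column contributes per-class F1 = 0, keeping the score defined under
extreme imbalance. Argmax ties break to the lowest class index.
"Ignoring the Null class" means dropping Null-labelled windows and
rescoring over the reduced, re-indexed class set — intended for models
trained without Null windows, not for post-hoc masking of a model that
could still predict Null.

## Synthetic data generator

The generator emulates the statistical structure of naturalistic
wearable datasets rather than their biomechanics:

* **Motifs** — each gesture class has one smooth multichannel template
  (sum of 4 random sinusoids, 0.5–3.5 cycles per motif, under a Hann
  envelope, unit RMS per channel), 32–56 samples long, i.e. longer
  than the 24-sample analysis window as real gestures usually are.
  Non-mirrored class pairs are redrawn until their pairwise
  correlation is below 0.8.
* **Imbalance** — the stream length is set so the Null share hits the
  0.75 target by construction; gesture instances are placed at random
  non-overlapping positions with Null gaps of at least one window, so
  last-sample labelling is unambiguous at boundaries.
* **Instance variability** — per-instance amplitude jitter and
  duration warp of ±20 % (linear resampling).
* **Modality ladder** — channels come in tagged groups
  (5 accelerometer-, 5 gyroscope-, 5 magnetometer-like by default)
  with amplitudes 1.0/0.7/0.4 and noise SD 0.05/0.15/0.30: every group
  carries class information, in strictly decreasing quality, so adding
  modalities should help and the fusion trend is testable.
* **Null background** — per-channel Gaussian noise plus a slow
  sinusoidal baseline drift (amplitude 0.05, 1–4 cycles per
  recording), standing in for posture changes and sensor bias.
* **Mirrored pairs** — optionally, class b's motif is exactly class
  a's reversed in time. The sorted per-channel sample distributions of
  the pair are then identical, so temporal order is the only cue
  separating them.
* **Missing data** — optional NaN runs (mean length 5 samples) to
  exercise interpolation.

Everything is deterministic per seed; the motif bank depends only on
the config seed, so train/validation/test recordings generated with
different placement seeds share one class vocabulary.

What the generator does **not** model: cross-channel correlation
structure of real IMUs, gravity and orientation effects, label noise
and annotation jitter, heterogeneous sample rates, or long-range
activity grammar. Results on it demonstrate that the implementation
learns and that the architectural contrasts behave as claimed — not
that any particular real-data score would be reached.

## Study protocols (`deepconvlstm.experiments`)

Problem sizes are chosen once for minute-scale single-CPU runs while
keeping the structure of the full-scale task:

* **Learnability** — default 5-class task, DeepConvLSTM scaled to 16
  maps / 32 cells, 40 gesture instances per class (~2,300 training
  windows), up to 50 epochs with patience 12 (validation F1 typically
  leaves the all-Null plateau after ~7 epochs). Reaches weighted
  F1 ≥ 0.9 on a held-out recording.
* **Temporal-order disambiguation** — two mirrored class pairs on a
  single 6-channel group; recurrent vs baseline readout at equal size
  (8 maps, 16 cells/units), 100 epochs. Compared on the mean per-class
  F1 over the mirrored classes.
* **Fusion ladder** — one recording set, channel subsets acc →
  acc+gyro → acc+gyro+mag, identical model size per rung (8 maps, 16
  cells), up to 110 epochs with early-stopping patience 25. Each rung
  trains under early stopping rather than a fixed small epoch budget:
  rungs with more channels have more parameters and converge more
  slowly, so a short fixed budget would confound the sensor set with
  optimisation progress.

## Numerical and design choices

* Double precision throughout; the convolution runs as P shifted
  map-mixing GEMMs and the LSTM batches its four input projections
  over all time steps, purely for speed — both are algebraically
  identical to the defining sums and tested against brute-force loops
  at 1e−10.
* Softmax is computed shift-invariantly (max subtraction).
* The correlation/convolution orientation of the kernel index is
  irrelevant for learned kernels; the implementation uses the sliding
  dot product over P consecutive samples.
* Checkpoints are single `.npz` archives holding every parameter array
  under its canonical name plus the JSON-encoded spec and seed;
  round-trips are bit-exact. Training history is a TSV log
  (epoch, loss, validation F1); reports are TSV tables.
* The conv-depth knob (`n_conv_layers`, 2–7) exists for depth sweeps;
  defaults follow the canonical 4-layer design.

## Known limitations

* At the scaled-down study sizes the fusion ladder's middle-rung gains are small relative
  to run-to-run training variance: with several clean accelerometer-like
  channels the one-group model already approaches the ceiling set by
  intrinsically ambiguous gesture-boundary windows, so adding a second
  group can gain ≈0 for some motif draws even though the full three-group
  model beats the one-group model consistently. Resolving such small gaps
  reliably would need replicate-averaged rungs (many training runs per
  comparison).

* CPU-only and single-threaded by design; the full-scale 113-channel
  configuration trains, but on a single CPU the intended use is the
  scaled models of the study protocols.
* Per-time-step (sample-wise) scoring, event-based metrics and AUC are
  out of scope; evaluation is window-level only.
* The "excluded Null" mode assumes the model was trained on the
  reduced class set; it does not re-map a Null-aware model.
* Resampling/decimation is upstream of the package: input is assumed
  to be at the target rate already.
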