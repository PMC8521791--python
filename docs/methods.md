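# Methods

## Problem and pipeline

`worktrack` classifies 8-s segments of a wrist-worn device's 9-channel
inertial stream into seven activity classes — walking (W_N), standing
(St_N), sitting (Si_N), lying (L_N) with neutral limbs, and the three
*working* activities reading (Re), typing (Ty) and writing (Wr), which are
posture-free classes (their sitting and standing variants share a label).
The pipeline is: 50 Hz stream → tumbling 2-s basic windows → per-window
features → 4-row feature matrices → classifier → streaming working judge.

## Features

For each full 100-sample window the package computes per-channel means μ
and sample standard deviations σ (N−1 denominator; the choice is a feature
convention, not an inference, and is fixed for reproducibility), and the
cooperativity vector ε: the unit eigenvector of the largest eigenvalue of
the 9×9 Pearson correlation matrix.  Numerical conventions:

- a zero-variance channel has undefined correlations; its off-diagonal
  entries are set to 0 (diagonal 1), keeping the matrix symmetric;
- eigenvectors are sign-ambiguous; the sign is flipped so the component of
  largest absolute value is positive (near-ties resolved toward the lowest
  index after rounding to 12 decimals).  For exactly degenerate spectra the
  output is the deterministic eigensolver choice under that rule and is
  convention-dependent;
- the raw signal is not filtered before feature extraction: over 2 s the
  low-order statistics describe the segment adequately, and filtering would
  add latency on-device.

Windows and 8-s samples are non-overlapping (tumbling) and never span an
episode boundary; trailing remainders are dropped.  Overlap would inflate
sample counts relative to the protocol arithmetic (a 3-min episode yields
⌊90/4⌋ = 22 samples) and correlate adjacent samples across train/test
splits.

## Classifiers

The shallow CNN family is implemented directly in NumPy (forward,
backprop, Adam); at this scale (≤ 3 tiny convolutions on a 4×27 input) a
deep-learning framework would add nothing but a dependency.

- Layer 1: 2D convolution, kernel 2 time rows × full feature width, 32
  filters, stride 1, ReLU.  Height-2 kernels give each filter 4 s of
  context — about one bout of a hand action — and output height 3.
- Layer 2: kernel 3×1 over all 32 maps, 32 filters, ReLU; the kernel spans
  the whole remaining time extent, so output height is 1.
- Layer 3: each output map mixes 3 adjacent input maps (a kernel of width 3
  along the map axis, zero-padded, one weight triple per map), ReLU.  This
  "groups of three adjacent maps" reading is one of two defensible
  interpretations of combining three channels; the alternative (width-3
  kernel along the feature axis in layer 1) is noted as open and the layer
  is isolated so it can be swapped.
- Head: flatten → dropout 0.2 → dense 64 ReLU → dense 7 softmax.

CNN(1)/(2)/(3) keep the first one/two/three convolutional layers.
Training: cross-entropy, Adam at 3e-3, batch 64, ≤ 100 epochs, early
stopping (patience 5) on a 10% stratified validation split.  The schedule
is this package's own: 3e-3 was chosen because at 1e-3 the depth-3 variant
can plateau in a poor optimum on small training sets, while 3e-3 converges
in fewer epochs with equal or better held-out accuracy.  All randomness
(init, shuffling, dropout, split) flows from one seed.

Baselines: SVM with RBF kernel, C = 1.5, "scale" bandwidth heuristic, and
native Platt-scaled probabilities; random forest with 200 trees, depth
≤ 10, library defaults otherwise.  Both consume the 4×n matrix flattened
to 4n (they are unstructured models).  All variants share per-feature
z-score normalization computed on the training split only.

## Evaluation

Stratified (by class, seeded shuffle) sample-level 5-fold CV and
leave-one-subject-out validation.  Fold confusions are summed before
computing aggregate metrics; per-fold metrics are retained for
distributional summaries.  The multiclass Matthews correlation is the R_K
multi-category statistic, which reduces exactly to the binary formula on
2×2 tables; a vanishing denominator (all truths or all predictions in one
class) yields 0 by convention.  Undefined per-class metrics (zero row or
column) are reported as absent and excluded from macro averages rather
than zeroed.  The working-status summary is the unweighted mean of recall
and precision over {Re, Ty, Wr}.

## Synthetic cohort

The generator emulates the 48-min session protocol: episodes of walking
(10 min), standing neutral (5), reading/typing/writing standing (3+3+3),
sitting neutral (5), reading/typing/writing sitting (3+3+3), lying (10).
Per class, each channel is baseline + gated sinusoids + correlated
Gaussian noise:

- class-specific attitude baselines (lying clearly apart; the working
  classes and standing close together);
- oscillators with class-specific dominant frequency, per-channel
  amplitude pattern (walking ~1.8 Hz, large, on acceleration and rotation
  rate; typing ~4 Hz loading vertical acceleration and z rotation; writing
  ~2.2 Hz on lateral acceleration and x rotation; reading ~0.6 Hz attitude
  rocking) and a Bernoulli bout gate on 0.5-s blocks (duty cycle 0.35
  reading / 0.6 writing / 0.8 typing, 1.0 otherwise);
- noise mixed through an invertible class-specific matrix, giving the
  correlation structure the cooperativity feature reads.

Constants were calibrated once against the generator's stated contract —
walking is the most distinct class mean and standing sits nearer typing
than walking — and then frozen.  Subject random effects: pace multiplier
lognormal(0, 0.15²) on all frequencies (the dominant effect), amplitude
multiplier lognormal(0, 0.2²), wrist-posture offsets N(0, 0.05² rad²).
Seeding is hierarchical (cohort → subject → episode) so any part is
reproducible in isolation.

What the generator does **not** emulate: biomechanically realistic arm
kinematics, transitions/interruptions inside episodes (drinking, fidgeting),
non-stationary pace, sensor drift, or dropped packets.  Synthetic classes
are cleaner and more stationary than real recordings, so absolute
accuracies here (≈ 0.95–1.0) exceed what the same models achieve on real
data; passing tests demonstrate that the pipeline is implemented correctly
and that relative orderings (sample-level CV ≥ LOSO; walking most
separable; St_N/Ty confusable) behave as expected, not that these
accuracies transfer to real wrists.

## Streaming path

The realtime buffer re-creates the training distribution online: feature
vectors of consecutive windows accumulate until four are held, then a
matrix is emitted and, in the default tumbling mode, the buffer clears
(one prediction per 8 s).  Any gap in window indices or an episode change
resets the buffer, so replaying a recorded session reproduces the batch
pipeline bit-for-bit.  A sliding mode (emit every 2 s once warm) trades
distribution fidelity for latency and is off by default.

The working judge flags time t as working when ≥ θ (default 0.5) of the
predictions in the trailing horizon (default 300 s, inclusive boundary)
are in {Re, Ty, Wr}; nudges fire when accumulated working time since the
last qualifying break (≥ 300 s non-working) reaches 3600 s.  Horizon,
threshold and nudge limits are product-level defaults, not fitted values.

## Problem sizes

Default experiments use the 12-subject cohort (4272 samples of 4×27 or
4×18), chosen to match the original study's cohort size; every
cross-validation scheme in the test suite and acceptance script runs on
this cohort in about a minute on one CPU core.

## Known limitations

- The CNN layer-3 semantics are one reading of an ambiguous description
  (see above).
- The SVM's Platt-scaled probabilities are calibrated on internal CV and
  can disagree with the raw decision function near ties; `predict_label`
  is always the argmax of `predict_proba` for consistency across variants.
- Feature matrices assume dense, gap-free sampling at the nominal rate;
  timestamps are validated but not used for resampling (observed jitter on
  the target hardware is < 10 ms, far below the 2-s window).
- `nudge_events` takes explicit times alongside flags because flag
  sequences alone carry no duration information.
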