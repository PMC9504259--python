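# Methods

This note documents the models, numerical conventions and design
decisions behind `emgfusion`. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Data model

A record is an `m × N` channel-by-sample array in volts with subject,
motion, optional side/session, trial and sampling-rate metadata
(`MultichannelEmgRecord`). On disk a record is a delimited numeric text
file, one column per channel; a manifest CSV
(`path, subject, motion, side, session, trial, rate`) binds labels.
Trial indices are 1-based in manifests (matching how acquisition
protocols count repetitions); arrays are 0-based internally.

Channel concatenation produces the single vector
`X = [x₁, …, x_m]` of length `m·N` analyzed by the image stream.
Length normalization uses linear interpolation with preserved
endpoints — the same "resize linearly without crops" convention used
for images — rather than truncation or padding.

Train/test splits are deterministic partitions by trial index: with
every (subject, motion, side) cell containing every named trial, the
split sizes are exact products (e.g. 50 subjects × 10 motions ×
2 sides × 3 trials = 3000 training items).

## Time-domain features (sequence stream)

Segmentation follows buffer semantics: window `j` starts at
`j·(L−V)` and the trailing window is zero-padded, giving
`S = ⌈N/(L−V)⌉` windows. The literal sliding-window count
`⌊(N−L)/(L−V)⌋+1` would give 8 windows for both canonical
configurations (N=640, L=85, V=12 and N=1500, L=200, V=30), whereas
both are specified as nine segments; the buffer convention reproduces
9 in both cases and is therefore used. Whether the trailing window is
padded or shortened is not specified anywhere; zero-padding is chosen
and applied uniformly.

Per window: MAV `(1/L)Σ|x_k|`; ZC counts strict sign flips with
`|x_k − x_{k+1}| ≥ θ`; SSC counts strict interior extrema with the
same step threshold; WL is `Σ|x_k − x_{k−1}|`. The threshold defaults
to θ = 0.01 (signal units, volts) for both ZC and SSC and is
configurable. A sample exactly at zero never participates in a
crossing (strict inequalities as defined). MAVS is the forward
difference of consecutive segment MAVs, defined for `i = 1…S−1`; the
final column is padded with 0 so the matrix stays rectangular at
`5 × S` per channel. Features are computed on raw amplitudes — no
filtering or rectification precedes extraction. Channel blocks are
concatenated channel-major (all segments of channel 1, then channel
2, …), giving `5 × (S·m)`.

## Scalograms (image stream)

The CWT is an FFT-domain analytic filter bank:
`W_s = ifft(fft(x) · ψ̂(s·ω))` with `ψ̂` supported on positive
frequencies and peak response normalized to 2 (so a unit-amplitude
sinusoid attains magnitude ≈ 1 at its matching row — one of the test
oracles). Families:

* **Morse** `ψ̂(ω) = U(ω)·a·ω^{P²/γ}·e^{−ω^γ}` with symmetry γ = 3 and
  time–bandwidth product P² = 60 by default (the common symmetric
  parameterization; the source recipe names the family but not the
  parameters, so these are exposed in `WaveletSpec`).
* **Gabor** — analytic Morlet-type window `e^{−(ω−ω₀)²/2}`, ω₀ = 6
  (equal time/frequency variance).
* **Bump** — compact window `exp(1 − 1/(1−u²))`, `u = (ω−μ)/σ`,
  μ = 5, σ = 0.6 (wide in time, narrow in frequency).

The scale grid is logarithmic with 10 voices per octave, descending
from the Nyquist frequency over `max(1, ⌊log₂N⌋ − 3)` octaves; signals
shorter than 16 samples are rejected. The pre-resize matrix is
`n_scales × N` (no fixed intermediate size is guaranteed; only the
post-resize contract matters). Rendering min–max normalizes the
magnitude **per image** (no global statistics exist at render time), maps
through a configurable colormap (default `viridis`, perceptually
uniform; the choice is recorded in experiment provenance since the CNN
trains on whatever map is configured) and bilinearly resizes to the
network input, 224 × 224 by default, without crops. A constant
magnitude normalizes to all-zeros by convention. In per-channel
(Case 2) mode each channel is normalized and rendered separately, then
stacked depthwise.

## Classifiers

Both streams are trained with Adam (β₁ = 0.9, interpreting the
recipe's "momentum 0.9" as Adam's first-moment decay, since Adam has
no classical momentum), cross-entropy loss, classic L2 regularization
(penalty added to the gradient) and a step schedule multiplying the
learning rate by `lr_decay` every `lr_step` epochs. No data
augmentation anywhere. Class labels are subject identities; motions,
sides and trials are within-class variation. Training is deterministic
given the seed (pure numpy; a fixed BLAS thread count is assumed for
bitwise reproducibility).

**EmgCNN.** The default backbone is a small residual network: a 3×3
stride-2 stem, 2×2 average pool, one identity residual block, another
pool, one stride-2 projection residual block, then a linear head. A
`deep_residual` variant appends two further stride-2 stages. No
pretrained weights are bundled — pretrained initialization is not part
of what this package contributes, and the desk-scale backbone trains
from scratch on a CPU in seconds. Two choices matter empirically on
scalograms and are defaults here:

* the head **flattens** the final feature map instead of global average
  pooling — subject identity lives in *where* spectral energy sits on
  the frequency axis, which pooling would discard;
* inputs are standardized per pixel with training-set statistics —
  scalogram images share a dominant colormap background, and removing
  it is the difference between learning in a few epochs and not
  learning at all at these scales (a batch-norm-free network was kept
  deliberately for determinism and simplicity).

Full-scale recipe defaults (`CnnConfig`): batch 20, initial LR 1e-4,
decay 0.2 per 5 epochs, L2 1e-4, 10 epochs. Desk-scale experiment
overrides (`ExperimentConfig`): width 8, LR 2e-3, decay 0.5 per 5,
12 epochs, 96 × 96 images — sized so a full synthetic run takes about
ten seconds while preserving every structural contract.

**EmgLSTM.** Sequence-to-one bidirectional LSTM: four-gate cells
(forget bias 1), the forward direction's final hidden state
concatenated with the backward direction's, then a linear map to class
logits. Sequences of different widths (e.g. 5 × 72 and 5 × 18) may
coexist in one dataset; batches are grouped by length. Feature rows
live on very different scales (volts vs integer counts), so inputs are
z-scored per feature row with training-set statistics by default.
Full-scale defaults (`LstmConfig`): input 5, 500 hidden units, batch
500, LR 0.01, decay 0.2 per 5, L2 1e-4, 300 epochs. Desk-scale
overrides: 64 hidden units, batch 64, decay 0.5 per 10, 40 epochs.

Backpropagation (im2col convolution gradients, BPTT) is verified
against central finite differences at tiny sizes in
`tests/test_nn_gradients.py`.

## Fusion and evaluation

Fusion operates on softmax score vectors (the only normalization both
streams natively emit) elementwise: sum for `EmgEnsembleNet-P`,
product for `EmgEnsembleNet-M`. Fused scores are reported raw — argmax
is scale-invariant — with ties broken toward the lowest class index.
Two provable properties are asserted over random score pairs: if both
streams agree on the argmax, both fusion modes preserve it; and
product fusion never selects a class either stream zeroes out (unless
all classes are zeroed).

Identification accuracy is percent correct over the test set.
Verification is one-vs-rest: class 1 is every record of the target
subject (split by trial); class 2 takes exactly one record per other
subject on each side of the split — the first (motion, side, trial) in
sorted order — because each enrolled subject contributes few samples.

Summary statistics use the sample (n−1) SD/variance; the paired t-test
is the classical two-sided test on (single-stream, ensemble) accuracy
pairs with df = n−1, with no multiplicity correction across the two
fusion modes (matching the single published p-value). The improvement
report computes, per dataset, the max ensemble-minus-stream gap and
best-ensemble-minus-baseline gaps. The bundled published accuracy
table reproduces the printed statistics to printed precision; note the
published "maximum improvement" figure for the 2-channel dataset is
not reconstructible from its printed table (the computed maximum gap
is 17.61), so the package reports what the table implies.

## Baselines

Feature sequences flatten row-major to `5·S·m` vectors. PCA uses
training-mean centering (scikit-learn, full SVD, deterministic sign
convention); LDA solves the generalized eigenproblem `S_b v = λ S_w v`
with the within-class scatter ridge-regularized by `1e-6 · tr(S_w)/d`
for invertibility on degenerate fixtures. "Closest distance to the
label data" is read as 1-nearest-neighbor against training samples in
the reduced space (L2), consistent with the `-L2` method names; a
class-centroid variant is available behind a flag since the phrasing
admits both readings. Ties resolve toward the lowest class via
label-sorted training rows. Dimension sweeps produce the
dimension-vs-accuracy curves; at full PCA rank 1-NN provably equals
raw-space 1-NN (orthogonal projections preserve distances), which the
tests assert.

## Synthetic data generator

Each channel of a record is white Gaussian noise band-passed
(4th-order Butterworth, zero-phase) to a subject-and-channel-specific
band, normalized to unit RMS, multiplied by a rest–burst–rest envelope
with raised-cosine ramps, scaled by a subject-specific channel gain at
0.2 V base amplitude, plus additive measurement noise. Subject
identity is thus encoded in spectral band positions and the
channel-gain pattern — mirroring the premise that inter-individual
differences (muscle composition, electrode coupling, habitual motion
style) manifest as spectral and amplitude signatures — while motion
identity is encoded in burst timing. `subject_separation` scales every
between-subject dispersion (0 collapses all subjects onto one profile,
so any classifier must fall to chance — a property the tests check
with a binomial band); `noise_level` scales trial-to-trial gain jitter
and measurement noise.

Defaults: 10 subjects × 3 motions × 5 trials, 8 channels, 640 samples
at 200 Hz (the armband-style geometry; frames at (85, 12) into 9
segments), separation 1.0, noise 0.1. The `cu-mini` preset uses
2 channels × 1500 samples at 187.5 Hz (the 8-second
rest(2 s)/burst(4 s)/rest(2 s) geometry downsampled; frames at
(200, 30) into 9 segments, sequences 5 × 18). Randomness is
hierarchical — profiles from the seed alone, each trial from
(seed, subject, motion, trial) — so enlarging a dataset never perturbs
existing records, and on-disk datasets are byte-identical across runs.

**What the generator does not emulate:** motor-unit action-potential
physiology, electrode lift-off and motion artifacts, inter-session
drift, crosstalk between channels, and realistic motion-class
structure (motions differ only in envelope timing). Passing tests
therefore demonstrate that the pipeline's machinery is correct and
that it recovers identity signals of the stated kind — not that it
attains any particular accuracy on recorded EMG. At the default
separation the synthetic task is easy enough that every method
saturates; the README's worked example deliberately uses a harder
setting to show non-trivial ordering.

## Problem sizes and reproducibility

The end-to-end synthetic experiment used by the tests and the
acceptance script runs 10 subjects × 3 motions × 5 trials (90 train /
60 test items), 96 × 96 Case-1 scalograms into the small residual CNN
and 64-unit BiLSTM, across three seeds — a deliberate desk-scale
choice; all structural contracts are identical at full scale.
Experiment runs write the resolved config, a config hash and the seed,
sufficient to replay a run exactly. The command-line surface is the
`emgfusion` click CLI (one subcommand per stage plus `run`), each
stage exchanging plain files so stages are independently inspectable.
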