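# emgfusion

Two-stream biometric **identification from surface EMG signals** with
score-level late fusion, as a tested, configurable Python library and CLI.

Surface electromyograms (sEMG) are attractive for biometrics because — unlike
faces, irises or fingerprints — they are not visually exposed and must be
measured in contact with the skin. `emgfusion` implements an ensemble
identification pipeline for multi-channel sEMG recordings organized as
*S subjects × M motions × T trials*:

1. **Image stream (EmgCNN).** The channel-wise concatenated signal
   `X = [x₁, x₂, …, x_m]` is mapped to a time–frequency scalogram by a
   continuous wavelet transform, `W(a,b) = ∫ f(t) ψ*((t−b)/a) dt / a`,
   with an analytic Morse (default), Gabor or Bump mother wavelet. The
   magnitude is rendered to a fixed-size colormapped image (224 × 224 × 3
   in concatenated "Case 1" mode, 224 × 224 × 3m in per-channel "Case 2"
   mode) and classified by a residual convolutional network.
2. **Sequence stream (EmgLSTM).** Each channel is cut into
   `S = ⌈N/(L−V)⌉` overlapping segments (length `L`, nominal overlap
   `V`), and five time-domain features are computed per segment: mean
   absolute value (MAV), MAV slope (MAVS), thresholded zero crossings
   (ZC), thresholded slope-sign changes (SSC) and waveform length (WL),
   with a 0.01 V threshold on ZC/SSC. The resulting `5 × (S·m)` sequence
   is classified by a sequence-to-one bidirectional LSTM. The canonical
   geometries are 5 × 72 (8 channels × 9 segments) and 5 × 18
   (2 channels × 9 segments).
3. **Late fusion.** The two streams' softmax score vectors are combined
   elementwise — sum (`EmgEnsembleNet-P`) or product (`EmgEnsembleNet-M`) —
   and the fused argmax is the identity decision.

PCA/LDA + minimum-L2-distance baselines (`EmgPCA-L2`, `EmgLDA-L2`) with
dimension sweeps, an identification/verification evaluation protocol, and
Table-style comparative statistics (group mean/SD/variance, two-sided paired
t-test, improvement reports) round out the toolkit.

No recorded dataset is required: a **synthetic EMG generator** emits
subject-distinguishable multi-channel records (band-limited noise with
subject-specific spectral bands and channel gains under a rest–burst–rest
envelope) in the same delimited-text + manifest format the loaders read.
The networks are implemented directly on numpy (im2col convolutions,
BPTT-unrolled LSTM, Adam) and train in seconds at desk scale on one CPU;
gradients are verified against finite differences in the test suite.

## Worked example

Train both streams and the fused ensembles on a synthetic 10-subject dataset
(3 motions × 5 trials, 8 channels, 640 samples at 200 Hz; trials 1–3 train,
4–5 test). Harder generator settings are chosen here so the streams do not
saturate:

```python
from emgfusion import ExperimentConfig, run_experiment

cfg = ExperimentConfig(seed=1,
                       generator={"subject_separation": 0.2, "noise_level": 0.8},
                       baselines=["pca"])
res = run_experiment(cfg, log=lambda *_: None)
print(res.table.to_frame().to_string(index=False))
```

```
  dataset           method  accuracy
synthetic           EmgCNN 40.000000
synthetic          EmgLSTM 50.000000
synthetic EmgEnsembleNet-P 55.000000
synthetic EmgEnsembleNet-M 55.000000
synthetic        EmgPCA-L2 48.333333
```

With 10 enrolled subjects chance is 10%. Both streams identify well above
chance, and fusing their scores lifts accuracy above either single stream
(55.0 vs 50.0) — the ensemble effect the pipeline is built around. At the
generator's default separation all methods reach 100% on this fixture.

The same experiment is available from the shell, along with each individual
stage (`synth`, `featurize`, `scalogram`, `train-cnn`, `train-lstm`, `fuse`,
`evaluate`, `baseline`, `report`):

```sh
emgfusion run --preset angeles-mini --seed 1 --out results/run1
emgfusion report            # statistics of the bundled published accuracy table
```

The `report` command prints, for the bundled benchmark accuracy table:

```
single_stream: mean 72.73  sd 14.53  variance 211.01
proposed: mean 83.49  sd 12.64  variance 159.71
total: mean 78.11  sd 13.85  variance 191.96
paired t-test: mean improvement 10.76, p = 0.0217, h = 1
```

i.e. fusing the two streams improves identification accuracy by 10.76
points on average across the two benchmark datasets, and the paired t-test
rejects equality of means at α = 0.05.

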