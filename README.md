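# myonet

Simultaneous knee-joint-angle regression and lower-limb movement
classification from raw 4-channel surface EMG, with a transfer-learning
CNN-LSTM (LRCN) at the core and the full experimental pipeline around it.

**Who it is for.** Researchers in rehabilitation engineering and
myoelectric control who want a self-contained, CPU-only, fully seeded
re-implementation of this two-task pipeline — either to run on their own
goniometer-annotated sEMG recordings (delimited text) or on the package's
synthetic generator, which emulates the acquisition protocol (walking,
sitting with knee extension, standing with knee flexion; 4 electrodes at
1000 Hz band-passed 20–460 Hz plus a knee goniometer).

**The model.** A three-block network over 256-sample windows
`x ∈ R^{256×4}`:

* *feature extractor* — four parallel per-channel stages
  (conv 20@11×1, stride 1 → ReLU → max-pool 4×1 → dropout 0.5),
  concatenated and passed through one more such stage → 16×20 feature maps;
* *angle head* — LSTM(32) → LSTM(64) → dense, linear activation, 256
  outputs: the angle sequence `θ̂ ∈ R^{256}` in degrees;
* *classification head* — flatten → dense → softmax over 3 classes.

Training is angle-first (Adam, lr 0.001, batch 25, MSE), then the
extractor is frozen bit-exactly and only the softmax head is trained —
the transfer-learning step that lets both tasks share one extractor.
Preprocessing follows the protocol: 256 ms windows with 64 ms overlap,
white-Gaussian-noise augmentation `D_v = D_o + wgn(m,n,p)` with `p` solved
per window for a 25 dB SNR target (×10 dataset), per-channel z-scoring fit
on training folds, 3-fold cross-validation. Predicted angle traces are
smoothed by an empirical iterative algorithm: cubic-spline interpolation
through midpoints of consecutive local extrema, two iterations. Metrics:
MAE as % of the angle range ± SD, per-class precision/recall/F1, accuracy,
row-normalized confusion matrix, Pearson r.

## Worked example

Run the full synthetic experiment (2 trials per class × 30 s, 3-fold CV,
30 epochs — about 10 minutes on one CPU):

```python
from myonet import RunConfig, SimConfig, LrcnConfig, run_experiment

report = run_experiment(RunConfig(
    out_dir="results/demo",
    n_trials_per_class=2,
    sim=SimConfig(duration_s=30.0, seed=1),
    lrcn=LrcnConfig(epochs=30),
    k=3,
    seed=0,
))
print(f"accuracy {report.accuracy:.2f}% +/- {report.accuracy_sd:.2f}")
print(f"MAE {report.mae_percent:.2f}% +/- {report.mae_percent_sd:.2f}")
print(f"Pearson r (post-smoothing) {report.pearson_r:.4f}")
```

prints

```
accuracy 99.46% +/- 0.19
MAE 9.04% +/- 0.50
Pearson r (post-smoothing) 0.9419
```

meaning: across the three folds the transferred classifier identifies the
movement of 99.5 % of held-out windows; the predicted knee-angle trace
deviates from the goniometer trace by 9.0 % of its dynamic range on
average; and the smoothed prediction tracks the actual angle with
r = 0.94. Per-fold reports, trained models (`.npz`, three named weight
blocks), the fold manifest and a log are written under `results/demo/`.

The same pipeline is scriptable from the shell:

```
myonet simulate --trials 2 --duration 30 --seed 1 --out data/
myonet run --trials 2 --duration 30 --epochs 30 --seed 0 --out results/demo
myonet smooth --iterations 2 predicted.tsv smoothed.tsv
```

Real recordings in delimited text (columns for the four electrodes and the
goniometer) load through `read_recording` with a configurable `ColumnMap`
(delimiter, header rows, column indices, sampling rate).

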