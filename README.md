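# mhcgt

Transformer-based classification of multi-temporal hyperspectral grassland
spectra.

Grassland monitoring increasingly relies on hyperspectral imaging: each
field sample yields a mean reflectance spectrum — here 125 bands covering
400–1000 nm — and the task is to identify which of seven forage species
(*Medicago sativa*, *Medicago ruthenica*, *Elymus canadensis*, *Hordeum
brevisubulatum*, *Medicago varia*, *Onobrychis viciaefolia*, *Bromus
ciliatus*) produced it, across two phenological phases (June growth,
August maturity) and two years (2020, 2021). This package is aimed at
remote-sensing and vegetation-ecology practitioners who want a tested,
self-contained implementation of the MHCgT workflow: a transformer encoder
operating on the spectrum as a sequence, together with the preprocessing,
training protocol, ablation and baseline-comparison harness around it —
plus a synthetic reflectance generator so the whole pipeline runs and is
testable without field data.

## The model

A spectrum is a univariate sequence `X ∈ R^{S×M}` with `S = 125` band
steps and `M = 1` variables per step. The network is

1. **positional encoding** — the fixed sinusoid
   `PE(pos, 2i) = sin(pos / 10000^{2i/M})`,
   `PE(pos, 2i+1) = cos(pos / 10000^{2i/M})` added to the input (for
   `M = 1` this is `sin(pos)`); it carries no trainable weights;
2. **4 pre-norm encoder blocks**, each: layer normalization →
   multi-head self-attention → dropout(0.25) → residual; then layer
   normalization → width-1 convolution to 64 channels with ReLU →
   dropout(0.25) → width-1 convolution back → residual. Attention uses
   `n = 8` heads of per-head width `D_k = 256`:

   ```
   head_i = softmax(Q W_i^Q (K W_i^K)^T / sqrt(D_k)) · (V W_i^V)
   MultiHeadSelfAttn(Q, K, V) = Concat(head_1, …, head_n) W°
   ```

3. **classification head** — global average pooling over the feature axis
   (a length-125 vector), a 125-unit dense layer with ReLU,
   dropout(0.4), and a 7-way dense layer under softmax.

With these settings the network has **exactly 74,768 trainable
parameters**; `closed_form_parameter_count` states the count symbolically
and the test suite checks it against direct enumeration. Training uses
Adam (lr 1e-3, β₁ 0.9, β₂ 0.98, ε 1e-9), batch size 125, 20 epochs,
early stopping with patience 10, and keeps the checkpoint with the best
validation accuracy (ties broken by the smaller validation loss).
Evaluation repeats stratified shuffle splits, reports accuracy
(proportion correct), per-species × per-phase tables, confusion matrices,
a training-fraction ablation, and a comparison against CNN-1D, LSTM-RNN,
SVM (C = 1.0), random forest and decision tree (max depth 10) baselines.

The network and the neural baselines are implemented on a small NumPy
reverse-mode autodiff module (`mhcgt.autodiff`); scikit-learn provides the
classical baselines and the stratified splitter, SciPy the
Savitzky–Golay filter.

## Worked example

```python
from mhcgt import (
    GeneratorConfig, generate_dataset, smooth_dataset,
    ModelConfig, TrainConfig, build_model, count_parameters,
    stratified_shuffle_split, run_repeated,
)

print("parameters:", count_parameters(build_model(ModelConfig())))

ds = smooth_dataset(generate_dataset(GeneratorConfig(samples_per_class_phase=100, seed=7)))
plan = stratified_shuffle_split(ds.labels, train_fraction=0.9, n_iterations=5, seed=1)
results, summary = run_repeated(ds, ModelConfig(), TrainConfig(seed=1), plan)
print("per-run test accuracy:", [round(r["test_accuracy"], 4) for r in results])
print("mean ± SD:", round(summary["mean_accuracy"], 4), round(summary["sd_accuracy"], 4))
```

prints (about three minutes on one CPU):

```
parameters: 74768
per-run test accuracy: [0.9607, 0.9607, 0.975, 0.9786, 0.9643]
mean ± SD: 0.9679 0.0084
```

i.e. the default 74,768-parameter network, trained five times on
independent 90/10 stratified splits of a reduced synthetic dataset
(2,800 spectra), classifies held-out spectra with ≈97% mean accuracy and
run-to-run spread under one percentage point. On the same splits a
depth-10 decision tree reaches ≈93%.

The same workflow is available from the shell:

```sh
mhcgt simulate --samples-per-class 100 --seed 7 --out raw.csv
mhcgt preprocess --in raw.csv --out smooth.csv --window 11 --order 2
mhcgt train --data smooth.csv --fraction 0.9 --iterations 5 --seed 1 --out runs/
mhcgt evaluate --model runs/best --data smooth.csv --out report/
mhcgt ablate --data smooth.csv --fractions 0.1,0.5,0.9 --reps 5 --out ablation/
mhcgt compare --data smooth.csv --methods MHCgT,SVM,RF,DT --out comparison/
```

Every command writes a manifest (configuration + seed + version) beside
its outputs; identical seeds reproduce outputs byte-for-byte in
single-threaded execution.

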