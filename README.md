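# ensplice

Splice-site detection with a stacking ensemble: eight small neural
sub-models (four convolutional, four dense) produce hard binary votes that
are stacked into an N×M matrix and combined by a logistic-regression
meta-model. Acceptor (consensus `AG`) and donor (consensus `GT`) sites are
handled as separate tasks. Ensemble presets are compared by stratified
five-fold cross-validation using both evaluation metrics (accuracy,
precision, sensitivity, specificity, MCC, F1, error rate) and pairwise
diversity metrics (correlation, double fault, disagreement, Yule's
Q-statistic).

The neural layers (Conv1D with "same" padding and ReLU, MaxPooling1D,
Flatten, Dropout, Dense), the Adam optimizer and the inverse-time-decay
learning-rate schedule are implemented in NumPy (`ensplice.nn`), so the
package has no deep-learning framework dependency and is fully
deterministic on CPU under fixed seeds.

## Layout

| module | contents |
| --- | --- |
| `ensplice.data_io` | FASTA / plain-text / CSV readers for labelled fixed-length windows, consensus validation, seeded balanced subsampling, one-hot encode/decode (A,C,G,T column order; unknown bases become all-zero rows) |
| `ensplice.synthetic` | PWM-based generator of balanced synthetic datasets with decoy negatives that also carry the consensus dinucleotide |
| `ensplice.nn` | minimal NumPy layer/optimizer engine |
| `ensplice.submodels` | the eight architecture presets (CNN1–4, DNN1–4), training config (batch 32, ≤30 epochs, early stopping), inverse time decay, train/predict/save/load |
| `ensplice.ensemble` | prediction stacking, meta-model fit/predict, the six membership presets ENS1–ENS6 |
| `ensplice.metrics` | confusion-count metrics and pairwise/ensemble diversity metrics with exact rational arithmetic where possible |
| `ensplice.crossval` | stratified k-fold CV of ensemble presets and ranking (accuracy, then double fault, then Q) |
| `ensplice.interpret` | position-frequency matrices for sequence logos; occlusion-based importance |
| `ensplice.pipeline` / `ensplice.cli` | end-to-end runs and the `ensplice` command |

## CLI

```bash
# balanced synthetic dataset (FASTA pair + manifest)
ensplice simulate --site donor --n 1000 --length 140 --signal 0.8 --seed 11 --out data/

# train one sub-model preset
ensplice train --preset CNN2 --site donor --data data/ --seed 11 --out model/

# predict with a saved model
ensplice predict --model model/ --site donor --data data/ --out preds.csv

# cross-validate ensemble presets and rank them
ensplice cv --site donor --ensembles ENS1,ENS2 --k 5 --data data/ --out cv_report.csv

# position-frequency matrix for logo tools
ensplice logo --site donor --data data/ --label-filter positive --out pfm.tsv

# full pipeline from a YAML config
ensplice run --config run.yaml
```

A minimal `run.yaml`:

```yaml
site_type: donor
ensemble: ENS2
out_dir: run_out
synthetic: {n_per_class: 500, window_length: 60, signal_strength: 1.0, seed: 7}
max_epochs: 5
```

## Notes

- Real-data dialects: 140-nt windows (acceptor consensus at positions
  69–70, donor at 71–72, 1-based) and 602-nt windows (consensus at
  301–302), plus a `generic` dialect with explicit window length and
  consensus positions.
- Balanced subsampling defaults to seed 123454.
- Training uses a two-unit sigmoid head with binary cross-entropy against
  two-column one-hot labels; prediction is the argmax with ties toward
  class 0.
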