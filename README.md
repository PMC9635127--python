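# pssmformer

An ultra-lightweight transformer classifier that distinguishes **adaptor
proteins** — the scaffolding proteins (e.g. MYD88, SHC1) that link binding
partners into signal-transduction complexes — from other proteins, using
**PSI-BLAST PSSM profiles** as input.

Adaptor-protein collections are awkward for sequence models: profile lengths
range from 18 to over 20,000 positions, forcing batch size 1, and adaptors
are outnumbered roughly 1:9. `pssmformer` addresses both with a compact
architecture and a matching training protocol:

- **Input** — one `N x 20` position-specific scoring matrix per protein
  (log-odds scores `P_ij` from PSI-BLAST), any `N >= 8`.
- **Model** — three convolutional blocks (20 kernels of width 3, layer
  normalisation `y = (x - E[x]) / sqrt(Var[x]) * γ + β`, ReLU, average
  pooling of kernel 2), one post-norm transformer encoder layer
  (`d = 20`, `h = 5` heads, `head_i = softmax(Q_i K_i^T / sqrt(d_k)) V_i`,
  feed-forward width `d_ff = 128`), global average pooling, and a two-layer
  FC head with dropout 0.5 and a sigmoid output. **12,137 trainable
  parameters ("12.1k") in total.**
- **Training** — weighted binary cross-entropy
  `L = -[w_pos · y · log x + w_neg · (1-y) · log(1-x)]` with inverse class
  frequency weights; Adam at `5e-4`, gradient accumulation over 24
  single-profile batches, learning-rate halving after 6 epochs without a
  validation-AUC improvement, early stopping after 20, best-validation-AUC
  checkpointing, stratified 5-fold cross-validation.
- **Evaluation** — sensitivity, specificity, accuracy, MCC, ROC/AUC and
  AUPRC, built for the 1:9 imbalance.

A synthetic-data generator reproduces the statistical shape of the real
cohort (log-uniform lengths from 18, 1:9 imbalance, conserved-column motifs
in positives), so the full pipeline is exercisable without any download. The
whole stack — forward pass, backpropagation, Adam — is plain numpy.

## Worked example

```python
from pssmformer import (GeneratorConfig, ModelConfig, TrainConfig, ScoredLabels,
                        generate_dataset, predict_proba, stratified_split,
                        summarize, train)

dataset = generate_dataset(GeneratorConfig(n_pos=40, n_neg=360, max_len=200, seed=7))
train_set, test_set = stratified_split(dataset, test_fraction=0.2, seed=0)
result = train(train_set, test_set, ModelConfig(), TrainConfig(epochs=10, seed=1))
probs = predict_proba(test_set, result.best_weights, result.model_config)
print(summarize(ScoredLabels(test_set.labels(), probs)))
```

prints (see `examples/03_train_and_evaluate.py`):

```
trained 10 epochs; best validation AUC 1.0000 at epoch 9
   sensitivity: 1.0000
   specificity: 0.9583
      accuracy: 0.9625
           auc: 1.0000
           mcc: 0.8348
         auprc: 1.0000
```

Sensitivity 1.0 with specificity 0.96 means every synthetic adaptor in the
held-out fifth was recovered at threshold 0.5 at the cost of three false
positives; AUC/AUPRC of 1.0 say the ranking separates the classes
completely — expected here, since the synthetic motif signal is strong.

The same workflow is available from the shell:

```bash
pssmformer simulate --n-pos 200 --n-neg 1800 --seed 42 -o data/
pssmformer train -i data/ -o run/ --cv 5
pssmformer evaluate -c run/fold0/checkpoint.npz -i data/ -o eval/
pssmformer count-params --d-ff 128
```

`examples/` contains one short narrative script per capability.

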