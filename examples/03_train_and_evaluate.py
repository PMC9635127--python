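"""Train the classifier on a small synthetic cohort and score it.

Uses the real protocol — batch size 1 with gradient accumulation, Adam with
plateau halving and early stopping, best-validation-AUC checkpointing — but
on a reduced cohort and epoch cap so the example runs in under a minute.
"""

from pssmformer import (
    GeneratorConfig,
    ModelConfig,
    ScoredLabels,
    TrainConfig,
    generate_dataset,
    predict_proba,
    stratified_split,
    summarize,
    train,
)

dataset = generate_dataset(GeneratorConfig(n_pos=40, n_neg=360, max_len=200, seed=7))
train_set, test_set = stratified_split(dataset, test_fraction=0.2, seed=0)
print(f"train {len(train_set)} / test {len(test_set)} "
      f"(class weights derived from {train_set.n_pos}:{train_set.n_neg})")

result = train(train_set, test_set, ModelConfig(), TrainConfig(epochs=10, seed=1))
print(f"trained {len(result.history)} epochs; "
      f"best validation AUC {result.best_auc:.4f} at epoch {result.best_epoch}")

probs = predict_proba(test_set, result.best_weights, result.model_config)
metrics = summarize(ScoredLabels(test_set.labels(), probs))
for k, v in metrics.items():
    print(f"  {k:>12s}: {v:.4f}")
# Sensitivity/specificity/accuracy are read at threshold 0.5; AUC and AUPRC
# are threshold-free and the ones to watch under 1:9 class imbalance.
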