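"""The imbalance-aware evaluation toolkit on a worked confusion matrix.

Reconstructs the counts behind a published independent test (155 adaptors,
1383 non-adaptors; 134 true positives, 239 false positives) and shows how
each metric reads the same predictions differently under 1:9 imbalance.
"""

import numpy as np

from pssmformer import (
    ConfusionMatrix,
    ScoredLabels,
    auc,
    auprc,
    basic_metrics,
    mcc,
    roc_curve,
)

cm = ConfusionMatrix(tp=134, fp=239, tn=1144, fn=21)
acc, sens, spec = basic_metrics(cm)
print(f"accuracy    {acc:.4f}   (misleading alone: 90% of items are negative)")
print(f"sensitivity {sens:.4f}   (fraction of adaptors recovered)")
print(f"specificity {spec:.4f}")
print(f"MCC         {mcc(cm):.4f}   (correlation; robust to the imbalance)")

# threshold-free view on synthetic scores with the same flavour
rng = np.random.default_rng(3)
labels = np.r_[np.ones(30, int), np.zeros(270, int)]
scores = np.r_[rng.normal(0.7, 0.2, 30), rng.normal(0.4, 0.2, 270)].clip(0, 1)
data = ScoredLabels(labels, scores)
pts = roc_curve(data)
print(f"\nROC curve: {len(pts)} points; AUC {auc(data):.4f}, AUPRC {auprc(data):.4f}")
# AUPRC is far below AUC on imbalanced data: precision punishes the many
# false positives that FPR barely notices.
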