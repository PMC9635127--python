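"""Training protocol: weighted BCE, batch-size-1 gradient accumulation,
Adam with plateau halving and early stopping, and the k-fold CV driver.

Profiles cannot be batched (their lengths differ wildly), so every gradient
is computed on a single profile and *summed* over groups of ``accumulation``
samples before one optimizer update — the accumulation emulates a batch of
24 without padding or windowing. The validation AUC drives both schedules:
the learning rate is halved after ``lr_patience`` epochs without a strict
improvement, and training stops after ``early_stop_patience`` such epochs.
The returned checkpoint is always the weights from the best-validation-AUC
epoch, not the last one.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np

from .grad import loss_and_grads, sigmoid, forward_logit
from .model import ModelConfig, Weights, init_weights
from .metrics import ScoredLabels, summarize
from .profiles import LabeledDataset, kfold_stratified


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 50
    lr_init: float = 5e-4
    accumulation: int = 24
    lr_patience: int = 6
    lr_factor: float = 0.5
    early_stop_patience: int = 20
    class_weights: tuple[float, float] | None = None  # None: derive from train counts
    threshold: float = 0.5
    seed: int = 42

    def __post_init__(self) -> None:
        if self.accumulation < 1:
            raise ValueError("accumulation must be >= 1")
        if not 0 < self.lr_factor < 1:
            raise ValueError("lr_factor must lie in (0, 1)")
        if self.lr_patience < 1 or self.early_stop_patience < 1:
            raise ValueError("patience values must be >= 1")
        if self.class_weights is not None and min(self.class_weights) <= 0:
            raise ValueError("class weights must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


def class_weights_from_counts(n_pos: int, n_neg: int) -> tuple[float, float]:
    """Inverse class frequencies: w_c = (n_pos + n_neg) / n_c.

    Report these rounded to two decimals; use them unrounded in the loss.
    """
    if n_pos < 1 or n_neg < 1:
        raise ValueError("both classes need at least one member")
    total = n_pos + n_neg
    return total / n_pos, total / n_neg


def weighted_bce(
    p: float, y: int, weights: tuple[float, float] = (1.0, 1.0)
) -> float:
    """Class-weighted binary cross-entropy for one prediction.

    L = -[w_pos * y * log p + w_neg * (1-y) * log(1-p)], with the log inputs
    clamped away from 0 for numerical safety.
    """
    if y not in (0, 1):
        raise ValueError(f"label must be 0 or 1, got {y!r}")
    w_pos, w_neg = weights
    eps = 1e-12
    p = min(max(float(p), eps), 1.0 - eps)
    return -(w_pos * y * np.log(p) + w_neg * (1 - y) * np.log(1.0 - p))


class Adam:
    """Standard Adam (beta1=0.9, beta2=0.999, eps=1e-8) over a weight dict."""

    def __init__(self, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m: Weights = {}
        self.v: Weights = {}

    def step(self, weights: Weights, grads: Weights, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            if k not in self.m:
                self.m[k] = np.zeros_like(g)
                self.v[k] = np.zeros_like(g)
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            weights[k] -= lr * mhat / (np.sqrt(vhat) + self.eps)


def accumulated_step(
    weights: Weights,
    samples: list[tuple[np.ndarray, int]],
    optimizer: Adam,
    lr: float,
    model_config: ModelConfig,
    class_weights: tuple[float, float],
    rng: np.random.Generator | None = None,
) -> float:
    """Sum per-sample gradients over one group, then apply one Adam update.

    Returns the summed loss of the group. The final partial group of an
    epoch is allowed (and still triggers an update).
    """
    if not samples:
        raise ValueError("accumulation group must be nonempty")
    total: Weights | None = None
    loss_sum = 0.0
    for x, y in samples:
        loss, grads, _ = loss_and_grads(
            x, y, weights, model_config, class_weights, training=True, rng=rng
        )
        loss_sum += loss
        if total is None:
            total = grads
        else:
            for k in total:
                total[k] += grads[k]
    assert total is not None
    optimizer.step(weights, total, lr)
    return loss_sum


@dataclass
class TrainState:
    """Mutable bookkeeping threaded through the epoch loop."""

    lr: float
    best_auc: float = -np.inf
    best_epoch: int = -1
    stale_lr: int = 0   # epochs since improvement, reset when lr is cut
    stale_stop: int = 0  # epochs since improvement, reset only on improvement
    history: list[dict] = field(default_factory=list)


def lr_schedule_step(state: TrainState, val_auc: float, config: TrainConfig) -> TrainState:
    """Plateau schedule: strict AUC improvement resets, stagnation halves lr."""
    if not 0.0 <= val_auc <= 1.0:
        raise ValueError("val_auc must lie in [0, 1]")
    if val_auc > state.best_auc:
        state.best_auc = val_auc
        # history is appended before the schedule runs, so the current epoch
        # is the last history row (or 0 when driven without a history)
        state.best_epoch = max(len(state.history) - 1, 0)
        state.stale_lr = 0
        state.stale_stop = 0
    else:
        state.stale_lr += 1
        state.stale_stop += 1
        if state.stale_lr >= config.lr_patience:
            state.lr *= config.lr_factor
            state.stale_lr = 0
    return state


def early_stop_check(state: TrainState, config: TrainConfig) -> bool:
    return state.stale_stop >= config.early_stop_patience


@dataclass
class TrainResult:
    best_weights: Weights
    best_epoch: int
    best_auc: float
    history: list[dict]
    model_config: ModelConfig
    train_config: TrainConfig


def predict_proba(
    dataset: LabeledDataset | list, weights: Weights, config: ModelConfig
) -> np.ndarray:
    """Evaluation-mode probabilities for every profile, in dataset order."""
    probs = []
    for prof in dataset:
        x = prof.scores if hasattr(prof, "scores") else np.asarray(prof, float)
        z, _ = forward_logit(x, weights, config, training=False)
        probs.append(sigmoid(z))
    return np.array(probs)


def train(
    train_set: LabeledDataset,
    val_set: LabeledDataset,
    model_config: ModelConfig | None = None,
    train_config: TrainConfig | None = None,
) -> TrainResult:
    """Run the full protocol on one train/validation split.

    Up to ``epochs`` epochs of accumulated Adam steps over a fresh seeded
    shuffle of the training set each epoch; per epoch the validation AUC is
    recorded and drives the learning-rate and early-stop schedules. The
    checkpoint of the best-validation-AUC epoch is returned with the full
    ``(epoch, loss, val_auc, lr)`` history.
    """
    model_config = model_config or ModelConfig()
    train_config = train_config or TrainConfig()
    if len(train_set) == 0 or len(val_set) == 0:
        raise ValueError("train and validation sets must be nonempty")
    val_labels = val_set.labels()
    if val_labels.min() == val_labels.max():
        raise ValueError("validation set has a single class; AUC is undefined")

    if train_config.class_weights is not None:
        cw = train_config.class_weights
    else:
        cw = class_weights_from_counts(train_set.n_pos, train_set.n_neg)

    ss = np.random.SeedSequence(train_config.seed)
    rng_init, rng_shuffle, rng_drop = (
        np.random.default_rng(c) for c in ss.spawn(3)
    )
    weights = init_weights(model_config, rng_init)
    optimizer = Adam()
    state = TrainState(lr=train_config.lr_init)
    best_weights = copy.deepcopy(weights)

    xs = [np.asarray(p.scores, dtype=float) for p in train_set]
    ys = [int(p.label) for p in train_set]
    n = len(xs)

    for epoch in range(train_config.epochs):
        order = rng_shuffle.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, train_config.accumulation):
            group = [(xs[i], ys[i]) for i in order[start : start + train_config.accumulation]]
            epoch_loss += accumulated_step(
                weights, group, optimizer, state.lr, model_config, cw, rng_drop
            )
        val_probs = predict_proba(val_set, weights, model_config)
        val_auc = _safe_auc(val_labels, val_probs)
        state.history.append(
            {
                "epoch": epoch,
                "loss": epoch_loss / n,
                "val_auc": val_auc,
                "lr": state.lr,
            }
        )
        if val_auc > state.best_auc:
            best_weights = copy.deepcopy(weights)
        lr_schedule_step(state, val_auc, train_config)
        if early_stop_check(state, train_config):
            break

    return TrainResult(
        best_weights=best_weights,
        best_epoch=state.best_epoch,
        best_auc=state.best_auc,
        history=state.history,
        model_config=model_config,
        train_config=train_config,
    )


def _safe_auc(labels: np.ndarray, probs: np.ndarray) -> float:
    from .metrics import auc

    return auc(ScoredLabels(labels, probs))


@dataclass
class CVResult:
    fold_results: list[TrainResult]
    fold_metrics: list[dict[str, float]]
    summary: dict[str, float]


def cross_validate(
    dataset: LabeledDataset,
    model_config: ModelConfig | None = None,
    train_config: TrainConfig | None = None,
    k: int = 5,
) -> CVResult:
    """Stratified k-fold CV; per fold, train and score the best checkpoint.

    Each fold trains with its own derived seed. The summary holds the mean
    over folds of sensitivity, specificity, accuracy, AUC, MCC and AUPRC at
    the configured threshold.
    """
    model_config = model_config or ModelConfig()
    train_config = train_config or TrainConfig()
    folds = kfold_stratified(dataset, k=k, seed=train_config.seed)
    fold_results, fold_metrics = [], []
    for f, (tr, va) in enumerate(folds):
        fold_cfg = replace(train_config, seed=train_config.seed + 1 + f)
        result = train(tr, va, model_config, fold_cfg)
        probs = predict_proba(va, result.best_weights, model_config)
        m = summarize(ScoredLabels(va.labels(), probs), train_config.threshold)
        fold_results.append(result)
        fold_metrics.append(m)
    summary = {
        key: float(np.mean([m[key] for m in fold_metrics]))
        for key in fold_metrics[0]
    }
    return CVResult(fold_results, fold_metrics, summary)
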