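"""Training objective, SGD loop, learning-rate sweep, and evaluation metrics.

The objective is a class-weighted binary cross-entropy on the bag
probability plus the two attention-sparsity penalties::

    loss_reg = loss_no_reg + R_L0 + R_mer

Training follows the bag-at-a-time protocol: plain SGD with batch size one,
random shuffling each epoch, online horizontal/vertical flip augmentation,
reverse class weighting against bag imbalance, and model selection by best
validation ROC-AUC across epochs.  Everything is reproducible from a single
integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn import metrics as skm

from .aggregation import (
    RegularizerWeights,
    l0_penalty,
    l0_smooth_penalty,
    mer_penalty,
    mer_penalty_gradient,
)
from .bags import Bag
from .models import MILModel
from .nn import sgd_step

__all__ = [
    "TrainConfig",
    "ClassWeights",
    "LossBreakdown",
    "MetricsReport",
    "TrainingHistory",
    "DEFAULT_LR_GRID",
    "reverse_class_weights",
    "bag_loss",
    "training_step",
    "train_model",
    "sweep_learning_rates",
    "evaluate",
    "predict_bags",
]

DEFAULT_LR_GRID = (1e-3, 5e-3, 1e-4, 5e-4, 1e-5, 5e-5, 1e-6, 5e-6)
_CLIP = 1e-7


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 50
    batch_bags: int = 1
    learning_rate: float = 1e-3
    momentum: float = 0.0
    weight_decay: float = 0.0
    lr_grid: tuple = DEFAULT_LR_GRID
    augment: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")


@dataclass(frozen=True)
class ClassWeights:
    """Reverse class weights: w_c = (n_neg + n_pos) / (2 * n_c)."""

    w_neg: float
    w_pos: float

    def __getitem__(self, label: int) -> float:
        return self.w_pos if label else self.w_neg


@dataclass(frozen=True)
class LossBreakdown:
    loss_no_reg: float
    r_l0: float
    r_mer: float

    @property
    def loss_reg(self) -> float:
        return self.loss_no_reg + self.r_l0 + self.r_mer


@dataclass
class MetricsReport:
    roc_auc: float                 # NaN when only one class is present
    accuracy: float
    recall: float
    precision: float
    f1: float
    confusion: np.ndarray          # 2x2 counts, rows = true, cols = predicted
    roc_points: list               # (fpr, tpr, threshold)


@dataclass
class TrainingHistory:
    epochs: list = field(default_factory=list)   # per-epoch summary dicts
    steps: list = field(default_factory=list)    # LossBreakdown per training step
    best_epoch: int = -1
    best_val_auc: float = float("nan")


def reverse_class_weights(n_neg: int, n_pos: int) -> ClassWeights:
    """Weights inversely proportional to bag counts, mean weight 1."""
    if n_neg < 1 or n_pos < 1:
        raise ValueError(f"both classes need >= 1 bag, got neg={n_neg}, pos={n_pos}")
    total = n_neg + n_pos
    return ClassWeights(w_neg=total / (2.0 * n_neg), w_pos=total / (2.0 * n_pos))


def bag_loss(bag_prob: float, label: int, weight: float,
             attention=None, reg: RegularizerWeights | None = None) -> LossBreakdown:
    """Weighted binary cross-entropy plus attention-sparsity penalties."""
    q = float(np.clip(bag_prob, _CLIP, 1.0 - _CLIP))
    loss = -weight * (np.log(q) if label else np.log(1.0 - q))
    r_l0 = r_mer = 0.0
    if attention is not None and reg is not None:
        if reg.l0_smooth:
            r_l0, _ = l0_smooth_penalty(attention, reg.lambda_l0, reg.l0_sigma)
        else:
            r_l0 = l0_penalty(attention, reg.lambda_l0)
        r_mer = mer_penalty(attention, reg.lambda_mer, reg.mer_sign)
    return LossBreakdown(loss_no_reg=float(loss), r_l0=r_l0, r_mer=r_mer)


def training_step(model: MILModel, bag: Bag, weight: float,
                  rng: np.random.Generator) -> LossBreakdown:
    """One forward/backward pass for a single bag; gradients are accumulated."""
    patches = bag.patches.astype(model.dtype) / 255.0 \
        if bag.patches.dtype == np.uint8 else bag.patches
    res = model.forward_bag(patches, train=True, rng=rng)
    reg = model.variant.regularizers
    breakdown = bag_loss(res.bag_probability, bag.label, weight,
                         attention=res.attention, reg=reg)
    q = float(np.clip(res.bag_probability, _CLIP, 1.0 - _CLIP))
    dq = weight * (q - bag.label) / (q * (1.0 - q))
    d_attention = None
    if res.attention is not None:
        d_attention = mer_penalty_gradient(res.attention, reg.lambda_mer, reg.mer_sign)
        if reg.l0_smooth:
            _, g = l0_smooth_penalty(res.attention, reg.lambda_l0, reg.l0_sigma)
            d_attention = d_attention + g
        # the exact L0 count is piecewise constant: zero gradient a.e.
    model.backward_bag(dq, d_attention=d_attention)
    return breakdown


def _flip_bag(bag: Bag, flip_v: bool, flip_h: bool) -> Bag:
    if not (flip_v or flip_h):
        return bag
    patches = bag.patches
    if flip_v:
        patches = patches[:, ::-1, :, :]
    if flip_h:
        patches = patches[:, :, ::-1, :]
    return Bag(patches=np.ascontiguousarray(patches), label=bag.label,
               patient_id=bag.patient_id, grid_shape=bag.grid_shape)


def train_model(model: MILModel, train_bags: list, val_bags: list,
                config: TrainConfig) -> TrainingHistory:
    """SGD training with per-epoch validation and best-AUC model selection.

    The model is left holding the weights of the epoch with the highest
    validation ROC-AUC (ties go to the earlier epoch).  With ``epochs=0``
    the weights are untouched and the history is empty.
    """
    if not train_bags:
        raise ValueError("training set is empty")
    labels = [b.label for b in train_bags]
    n_pos = sum(labels)
    if n_pos == 0 or n_pos == len(labels):
        raise ValueError("training set must contain both classes")
    weights = reverse_class_weights(len(labels) - n_pos, n_pos)

    rng = np.random.default_rng(config.seed)
    history = TrainingHistory()
    best_weights = None
    velocities = None
    params = model.params()
    for epoch in range(config.epochs):
        order = rng.permutation(len(train_bags))
        epoch_losses = []
        for idx in order:
            bag = train_bags[idx]
            if config.augment:
                bag = _flip_bag(bag, rng.random() < 0.5, rng.random() < 0.5)
            model.zero_grads()
            breakdown = training_step(model, bag, weights[bag.label], rng)
            velocities = sgd_step(params, config.learning_rate, config.momentum,
                                  config.weight_decay, velocities)
            history.steps.append(breakdown)
            epoch_losses.append(breakdown.loss_reg)
        entry = {"epoch": epoch, "train_loss": float(np.mean(epoch_losses))}
        if val_bags:
            report = evaluate(model, val_bags)
            entry["val_auc"] = report.roc_auc
            entry["val_accuracy"] = report.accuracy
            # ties go to the later epoch: among equal-AUC epochs the most
            # trained model is kept (small validation sets tie often)
            if not np.isnan(report.roc_auc) and (
                    np.isnan(history.best_val_auc)
                    or report.roc_auc >= history.best_val_auc):
                history.best_val_auc = report.roc_auc
                history.best_epoch = epoch
                best_weights = model.get_weights()
        history.epochs.append(entry)
    if best_weights is not None:
        model.set_weights(best_weights)
    return history


def sweep_learning_rates(model_factory, train_bags, val_bags, grid,
                         config: TrainConfig):
    """Train one model per learning rate; return (table, best model, history).

    ``model_factory`` builds a freshly initialised model (same seed each
    call) so every grid point starts from identical weights.  The winner is
    the grid point with the highest validation AUC.
    """
    grid = tuple(grid)
    if not grid:
        raise ValueError("learning-rate grid is empty")
    table, best = [], None
    for lr in grid:
        model = model_factory()
        cfg = TrainConfig(epochs=config.epochs, learning_rate=lr,
                          momentum=config.momentum,
                          weight_decay=config.weight_decay,
                          augment=config.augment, seed=config.seed)
        history = train_model(model, train_bags, val_bags, cfg)
        table.append({"lr": lr, "best_val_auc": history.best_val_auc,
                      "best_epoch": history.best_epoch})
        if best is None or _better(history.best_val_auc, best[2].best_val_auc):
            best = (lr, model, history)
    return table, best[1], best[2]


def _better(a: float, b: float) -> bool:
    if np.isnan(b):
        return not np.isnan(a)
    return not np.isnan(a) and a > b


def predict_bags(model: MILModel, bags: list) -> np.ndarray:
    """Bag probabilities for a list of bags (inference mode, no dropout)."""
    scores = []
    for bag in bags:
        patches = bag.patches.astype(model.dtype) / 255.0 \
            if bag.patches.dtype == np.uint8 else bag.patches
        scores.append(model.forward_bag(patches).bag_probability)
    return np.asarray(scores)


def evaluate(model_or_scores, bags_or_labels, threshold: float = 0.5) -> MetricsReport:
    """Five-metric report: ROC-AUC, accuracy, recall, precision, F1.

    Accepts either ``(model, bags)`` or ``(scores, labels)``.  AUC uses the
    rank-equivalent trapezoidal ROC integral (ties get half credit); the
    thresholded metrics use ``threshold`` with positive = abnormal.  With a
    single-class truth the AUC is reported as NaN and the rest computed.
    """
    if isinstance(model_or_scores, MILModel):
        scores = predict_bags(model_or_scores, bags_or_labels)
        labels = np.array([b.label for b in bags_or_labels])
    else:
        scores = np.asarray(model_or_scores, dtype=float)
        labels = np.asarray(bags_or_labels, dtype=int)
    if scores.size == 0:
        raise ValueError("cannot evaluate an empty set")
    pred = (scores >= threshold).astype(int)
    confusion = skm.confusion_matrix(labels, pred, labels=[0, 1])
    if labels.min() == labels.max():
        auc, roc_points = float("nan"), []
    else:
        auc = float(skm.roc_auc_score(labels, scores))
        fpr, tpr, thr = skm.roc_curve(labels, scores)
        roc_points = list(zip(fpr.tolist(), tpr.tolist(), thr.tolist()))
    return MetricsReport(
        roc_auc=auc,
        accuracy=float(skm.accuracy_score(labels, pred)),
        recall=float(skm.recall_score(labels, pred, zero_division=0)),
        precision=float(skm.precision_score(labels, pred, zero_division=0)),
        f1=float(skm.f1_score(labels, pred, zero_division=0)),
        confusion=confusion,
        roc_points=roc_points,
    )
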