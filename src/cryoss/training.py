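"""Training protocol: weighted cross-entropy, LR decay, and the epoch loop.

The loss is a class-weighted cross-entropy over voxels, with weights
(0.25, 0.5, 0.25) for (helix, sheet, others) -- roughly the reciprocal
class abundances -- normalized as a weighted mean over contributing voxels
so the scale is independent of chunk occupancy.  Unassigned voxels carry
no loss.  Adam starts at lr 1e-3 with no weight decay; the rate halves
whenever the mean training loss has not improved for 4 consecutive epochs
and training stops once a halving takes it below 1e-5.  The parameters of
the epoch with the lowest validation loss are returned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chunking import Box, augment, center_crop
from .labeling import UNASSIGNED
from .model import (
    VoxelClassifier,
    calibrate_batchnorm,
    clone_parameters,
    restore_parameters,
)
from .nn import Adam, softmax_channels

DEFAULT_CLASS_WEIGHTS = (0.25, 0.5, 0.25)


@dataclass
class TrainConfig:
    class_weights: tuple[float, float, float] = DEFAULT_CLASS_WEIGHTS
    lr_init: float = 1e-3
    lr_factor: float = 0.5
    lr_patience: int = 4
    lr_min: float = 1e-5
    max_epochs: int = 300
    batch_boxes: int = 180  # value used at full scale; reduce for CPU runs
    val_frac: float = 0.10
    weight_decay: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not all(w > 0 for w in self.class_weights):
            raise ValueError("class weights must be positive")
        if not 0.0 < self.val_frac < 1.0:
            raise ValueError("val_frac must be in (0, 1)")
        if self.lr_min >= self.lr_init:
            raise ValueError("lr_min must be below lr_init")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    learning_rate: list[float] = field(default_factory=list)
    selected_epoch: int = -1  # 0-based index of the min-validation-loss epoch


def split_train_val(
    map_ids: list, val_frac: float = 0.10, seed: int = 0
) -> tuple[list, list]:
    """Disjoint, exhaustive split at the whole-map level.

    The validation set holds round(val_frac * N) maps (at least one);
    deterministic in ``seed``.
    """
    if len(map_ids) < 2:
        raise ValueError("need at least 2 maps to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(map_ids))
    n_val = max(1, int(np.floor(val_frac * len(map_ids) + 0.5)))
    val = [map_ids[i] for i in sorted(order[:n_val])]
    train = [map_ids[i] for i in sorted(order[n_val:])]
    return train, val


def weighted_cross_entropy(
    probs: np.ndarray,
    labels: np.ndarray,
    weights: tuple[float, float, float] = DEFAULT_CLASS_WEIGHTS,
) -> float:
    """Weighted-mean cross-entropy over assigned voxels.

    ``probs`` is (3, ...) class probabilities, ``labels`` the matching code
    array; Unassigned voxels are skipped.  Returns 0.0 for all-Unassigned
    input.  Invariant under rescaling of the weights.
    """
    labels = np.asarray(labels)
    if probs.shape[1:] != labels.shape:
        raise ValueError(
            f"probs spatial shape {probs.shape[1:]} != labels shape {labels.shape}"
        )
    mask = labels != UNASSIGNED
    if not mask.any():
        return 0.0
    lab = labels[mask]
    p = np.moveaxis(probs, 0, -1)[mask]  # (n, 3)
    w = np.asarray(weights, dtype=float)[lab]
    nll = -np.log(np.maximum(p[np.arange(len(lab)), lab], 1e-30))
    return float((w * nll).sum() / w.sum())


@dataclass
class LRState:
    """Patience-based halving schedule driven by the mean training loss."""

    lr: float
    factor: float = 0.5
    patience: int = 4
    lr_min: float = 1e-5
    best: float | None = None
    counter: int = 0
    stop: bool = False


def lr_schedule_step(state: LRState, epoch_train_loss: float) -> LRState:
    """Advance the schedule by one epoch.

    The first epoch seeds the best-so-far loss and counts toward patience
    (there is no prior epoch to improve on); afterwards the counter resets
    on strict improvement and increments otherwise.  At ``patience``
    non-improving epochs the rate halves and the counter resets; training
    stops once the halved rate falls below ``lr_min``.
    """
    if state.best is None:
        state.best = epoch_train_loss
        state.counter = 1
    elif epoch_train_loss < state.best:
        state.best = epoch_train_loss
        state.counter = 0
    else:
        state.counter += 1
    if state.counter >= state.patience:
        state.lr *= state.factor
        state.counter = 0
        if state.lr < state.lr_min:
            state.stop = True
    return state


class TrainingError(RuntimeError):
    pass


def _batch_loss_and_grad(
    model: VoxelClassifier,
    density: np.ndarray,
    labels: np.ndarray,
    weights: tuple[float, float, float],
) -> float:
    """Forward + backward for one batch; returns the weighted-mean loss."""
    x = density[:, None].astype(model.dtype)
    logits = model.forward_logits(x, training=True)
    probs = softmax_channels(logits)
    mask = labels != UNASSIGNED
    if not mask.any():
        return 0.0
    w_map = np.zeros(labels.shape, dtype=np.float64)
    safe = np.where(mask, labels, 0)
    w_map[mask] = np.asarray(weights)[safe[mask]]
    w_sum = w_map.sum()
    onehot = np.eye(model.config.n_classes)[safe].transpose(0, 4, 1, 2, 3)
    dlogits = (w_map[:, None] * (probs - onehot) / w_sum).astype(model.dtype)
    aux_logits = model.forward_aux_logits()
    d_aux = None
    if aux_logits:
        # deep supervision: average the main and auxiliary losses
        share = 1.0 / (1 + len(aux_logits))
        dlogits *= share
        d_aux = {}
        for j, lg in aux_logits.items():
            pj = softmax_channels(lg)
            d_aux[j] = (share * w_map[:, None] * (pj - onehot) / w_sum).astype(
                model.dtype
            )
    model.backward(dlogits, d_aux)
    p_true = np.take_along_axis(probs, safe[:, None], axis=1)[:, 0]
    nll = -np.log(np.maximum(p_true[mask], 1e-30))
    return float((w_map[mask] * nll).sum() / w_sum)


def validation_loss(
    model: VoxelClassifier,
    boxes: list[Box],
    weights: tuple[float, float, float],
    batch: int = 4,
) -> float:
    """Mean weighted cross-entropy over center-cropped boxes (no augmentation)."""
    losses = []
    for start in range(0, len(boxes), batch):
        chunks = [center_crop(b) for b in boxes[start : start + batch]]
        x = np.stack([c.density for c in chunks])[:, None].astype(model.dtype)
        logits = model.forward_logits(x, training=False)
        probs = softmax_channels(logits)
        for s, c in enumerate(chunks):
            losses.append(weighted_cross_entropy(probs[s], c.labels, weights))
    return float(np.mean(losses)) if losses else 0.0


def train(
    model: VoxelClassifier,
    boxes_by_map: dict[object, list[Box]],
    config: TrainConfig,
    max_epochs: int | None = None,
) -> tuple[VoxelClassifier, TrainHistory]:
    """Train on normalized, filtered, labeled boxes grouped by source map.

    Maps are split into train/validation sets; each epoch shuffles the
    training boxes, draws one augmented 40^3 chunk per box, and applies
    Adam updates per batch.  Validation uses center crops without
    augmentation.  Returns the model restored to the epoch with the lowest
    validation loss, plus the full history.
    """
    if max_epochs is None:
        max_epochs = config.max_epochs
    n_boxes = sum(len(v) for v in boxes_by_map.values())
    if n_boxes == 0:
        raise TrainingError(
            "no boxes to train on (all were filtered out as >= 95% Unassigned)"
        )
    train_ids, val_ids = split_train_val(
        sorted(boxes_by_map, key=str), config.val_frac, config.seed
    )
    train_boxes = [b for mid in train_ids for b in boxes_by_map[mid]]
    val_boxes = [b for mid in val_ids for b in boxes_by_map[mid]]
    if not train_boxes:
        raise TrainingError(
            f"empty training partition: {len(train_ids)} train maps contributed "
            f"0 of {n_boxes} boxes"
        )
    rng = np.random.default_rng(config.seed)
    optimizer = Adam(
        model.params(), lr=config.lr_init, weight_decay=config.weight_decay
    )
    schedule = LRState(
        lr=config.lr_init,
        factor=config.lr_factor,
        patience=config.lr_patience,
        lr_min=config.lr_min,
    )
    history = TrainHistory()
    best_val = np.inf
    best_params = clone_parameters(model)
    for epoch in range(max_epochs):
        order = rng.permutation(len(train_boxes))
        epoch_losses = []
        for start in range(0, len(order), config.batch_boxes):
            batch_idx = order[start : start + config.batch_boxes]
            chunks = [augment(train_boxes[i], rng) for i in batch_idx]
            density = np.stack([c.density for c in chunks])
            labels = np.stack([c.labels for c in chunks])
            model.zero_grad()
            loss = _batch_loss_and_grad(
                model, density, labels, config.class_weights
            )
            optimizer.lr = schedule.lr
            optimizer.step()
            epoch_losses.append(loss)
        train_loss = float(np.mean(epoch_losses))
        # refresh batch-norm statistics on a fixed sample of training chunks
        # so eval-mode validation and inference see calibrated activations
        cal = [center_crop(b).density for b in train_boxes[:16]]
        calibrate_batchnorm(
            model, [np.stack(cal[i : i + 4]) for i in range(0, len(cal), 4)]
        )
        val_loss = validation_loss(model, val_boxes, config.class_weights)
        history.train_loss.append(train_loss)
        history.val_loss.append(val_loss)
        history.learning_rate.append(schedule.lr)
        if val_loss < best_val:
            best_val = val_loss
            best_params = clone_parameters(model)
            history.selected_epoch = epoch
        lr_schedule_step(schedule, train_loss)
        if schedule.stop:
            break
    restore_parameters(model, best_params)
    return model, history
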