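"""Training loop, evaluation and the training-set-size benchmark.

Training is plain mini-batch Adam on the family's loss (summed cross
entropies for the segmentation and binned families, mean squared error for
regression), with optional label-consistent augmentation drawn per sample.
Inputs are normalized to [0, 1].  Everything is driven by one seeded
generator, so (seed, config) -> identical histories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence

import numpy as np
import pandas as pd

from .augmentation import AugmentationConfig, TrainingSample, augment_sample
from .geometry import (NO_DETECTION, largest_component, quadrant_of_angle)
from .metrics import center_error, ellipse_iou, mask_iou
from .networks import (
    binned_loss_grad,
    decode_binned,
    decode_regression,
    regression_loss_grad,
    segmentation_loss_grad,
    segmentation_to_ellipse,
)
from .nn import Adam, SGD
from .nn.functional import softmax


@dataclass
class Hyperparams:
    learning_rate: float = 1e-4
    batch_size: int = 16
    epochs: int = 20
    optimizer: str = "adam"
    seed: int = 0

    def __post_init__(self):
        if min(self.learning_rate, self.batch_size, self.epochs) <= 0:
            raise ValueError("hyperparameters must be positive")


@dataclass
class TrainingHistory:
    epochs: List[int] = field(default_factory=list)
    train_loss: List[float] = field(default_factory=list)
    val_loss: List[float] = field(default_factory=list)
    val_center_error_px: List[float] = field(default_factory=list)
    val_iou: List[float] = field(default_factory=list)
    best_epoch: int = -1
    seed: int = 0

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "epoch": self.epochs, "train_loss": self.train_loss,
            "val_loss": self.val_loss,
            "val_center_error_px": self.val_center_error_px,
            "val_iou": self.val_iou})


def _inputs(samples: Sequence[TrainingSample]) -> np.ndarray:
    x = np.stack([s.frame for s in samples]).astype(np.float32) / 255.0
    return x[:, None, :, :]


def _loss_and_backward(model, batch: Sequence[TrainingSample]) -> float:
    """Forward + loss + backward for one batch, family-dispatched."""
    x = _inputs(batch)
    if model.family == "segmentation":
        mask_true = np.stack([s.mask for s in batch]).astype(np.int64)
        dir_true = np.array([int(s.direction) for s in batch])
        ml, dl = model.forward(x, training=True)
        loss, gm, gd = segmentation_loss_grad(ml, dl, mask_true, dir_true)
        model.backward(gm, gd)
    elif model.family == "binned":
        targets = {name: np.array([model.heads.encode(name, _param(s, name))
                                   for s in batch])
                   for name in model.heads.ranges}
        scores = model.forward(x, training=True)
        loss, grads = binned_loss_grad(scores, targets)
        model.backward(grads)
    else:  # regression
        t = np.stack([s.ellipse.as_vector() for s in batch])
        out = model.forward(x, training=True)
        loss, g = regression_loss_grad(out, t)
        model.backward(g)
    return loss


def _param(s: TrainingSample, name: str) -> float:
    e = s.ellipse
    return {"x": e.x, "y": e.y, "major": e.major, "minor": e.minor,
            "theta": e.theta_deg}[name]


def _val_loss(model, samples, batch_size: int) -> float:
    total, n = 0.0, 0
    for i in range(0, len(samples), batch_size):
        batch = samples[i:i + batch_size]
        x = _inputs(batch)
        if model.family == "segmentation":
            ml, dl = model.forward(x)
            loss, _, _ = segmentation_loss_grad(
                ml, dl, np.stack([s.mask for s in batch]).astype(np.int64),
                np.array([int(s.direction) for s in batch]))
        elif model.family == "binned":
            scores = model.forward(x)
            targets = {name: np.array([model.heads.encode(name, _param(s, name))
                                       for s in batch])
                       for name in model.heads.ranges}
            loss, _ = binned_loss_grad(scores, targets)
        else:
            loss, _ = regression_loss_grad(
                model.forward(x), np.stack([s.ellipse.as_vector() for s in batch]))
        total += loss * len(batch)
        n += len(batch)
    return total / max(n, 1)


def _snapshot(model):
    return ([p.value.copy() for p in model.params()],
            [(bn.running_mean.copy(), bn.running_var.copy())
             for bn in model.bn_layers()])


def _restore(model, snap) -> None:
    values, buffers = snap
    for p, v in zip(model.params(), values):
        p.value[...] = v
    for bn, (m, v) in zip(model.bn_layers(), buffers):
        bn.running_mean[...] = m
        bn.running_var[...] = v


def train(model, dataset: Sequence[TrainingSample], hp: Hyperparams,
          aug: Optional[AugmentationConfig] = None,
          val_dataset: Optional[Sequence[TrainingSample]] = None,
          checkpoint: str = "val_loss",
          verbose: bool = False) -> TrainingHistory:
    """Optimize the family's loss; returns the history and leaves the model
    at its best-validation weights (final weights if no validation set).

    ``checkpoint`` selects which validation quantity picks the kept epoch:
    ``val_loss`` (default) or ``center_error`` — for tracking use the summed
    loss is dominated by the direction term, so selecting on the median
    validation center error keeps the best *tracking* model.
    """
    if len(dataset) == 0:
        raise ValueError("empty training dataset")
    if val_dataset:
        train_ids = {s.sample_id for s in dataset}
        overlap = train_ids & {s.sample_id for s in val_dataset}
        if overlap:
            raise ValueError(f"validation ids leak into training: {sorted(overlap)[:5]}")
    if checkpoint not in ("val_loss", "center_error"):
        raise ValueError(f"unknown checkpoint criterion {checkpoint!r}")
    rng = np.random.default_rng(hp.seed)
    opt_cls = {"adam": Adam, "sgd": SGD}[hp.optimizer]
    opt = opt_cls(model.params(), lr=hp.learning_rate)
    history = TrainingHistory(seed=hp.seed)
    best = (math.inf, None)
    for epoch in range(hp.epochs):
        order = rng.permutation(len(dataset))
        losses = []
        for i in range(0, len(order), hp.batch_size):
            batch = [dataset[j] for j in order[i:i + hp.batch_size]]
            if aug is not None:
                batch = [augment_sample(s, aug, rng) for s in batch]
            opt.zero_grad()
            loss = _loss_and_backward(model, batch)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss {loss} at epoch {epoch}, step {i // hp.batch_size}")
            opt.step()
            losses.append(loss)
        history.epochs.append(epoch)
        history.train_loss.append(float(np.mean(losses)))
        if val_dataset:
            vloss = _val_loss(model, val_dataset, hp.batch_size)
            _, agg = evaluate(model, val_dataset)
            history.val_loss.append(vloss)
            history.val_center_error_px.append(agg["center_error_median_px"])
            history.val_iou.append(agg["iou_mean"])
            score = vloss if checkpoint == "val_loss" else \
                agg["center_error_median_px"]
            if math.isfinite(score) and score < best[0]:
                best = (score, _snapshot(model))
                history.best_epoch = epoch
        else:
            history.val_loss.append(float("nan"))
            history.val_center_error_px.append(float("nan"))
            history.val_iou.append(float("nan"))
        if verbose:
            print(f"epoch {epoch}: train {history.train_loss[-1]:.4f} "
                  f"val {history.val_loss[-1]:.4f} "
                  f"center {history.val_center_error_px[-1]:.2f}px "
                  f"iou {history.val_iou[-1]:.3f}")
    if best[1] is not None:
        _restore(model, best[1])
    return history


# ---------------------------------------------------------------------------
# Evaluation


def predict_sample(model, sample: TrainingSample):
    """Run one sample through the model; returns (fit, predicted_mask)."""
    x = _inputs([sample])
    if model.family == "segmentation":
        ml, dl = model.forward(x)
        prob_fg = softmax(ml[0], axis=0)[1]
        pred_mask = largest_component((prob_fg > 0.5).astype(np.uint8))
        return segmentation_to_ellipse(ml[0], dl[0]), pred_mask
    if model.family == "binned":
        scores = model.forward(x)
        vals = decode_binned({k: v[0] for k, v in scores.items()}, model.heads)
        return vals, None
    out = model.forward(x)
    return decode_regression(out[0]), None


def evaluate(model, dataset: Sequence[TrainingSample]):
    """Per-sample center error, IoU and direction hit, plus aggregates.

    IoU is mask IoU for the segmentation family (predicted vs ground-truth
    mask) and rasterized-ellipse IoU for families that output a full
    six-parameter fit.  NoDetection frames are counted and excluded from
    the error aggregates.
    """
    rows = []
    for s in dataset:
        pred, pred_mask = predict_sample(model, s)
        row = {"sample_id": s.sample_id, "detected": True,
               "center_error_px": np.nan, "iou": np.nan,
               "direction_correct": np.nan}
        if pred is NO_DETECTION:
            row["detected"] = False
        elif isinstance(pred, dict):  # binned partial fit
            if "x" in pred and "y" in pred:
                row["center_error_px"] = math.hypot(pred["x"] - s.ellipse.x,
                                                    pred["y"] - s.ellipse.y)
            if "theta" in pred:
                row["direction_correct"] = float(
                    quadrant_of_angle(pred["theta"]) == s.direction)
        else:
            row["center_error_px"] = center_error(pred, s.ellipse)
            if pred_mask is not None:
                row["iou"] = mask_iou(pred_mask, s.mask)
            else:
                row["iou"] = ellipse_iou(pred, s.ellipse, s.frame.shape)
            if hasattr(pred, "sin_theta"):
                row["direction_correct"] = float(
                    quadrant_of_angle(pred.theta_deg) == s.direction)
        rows.append(row)
    df = pd.DataFrame(rows)
    det = df[df.detected]
    agg = {
        "n": len(df),
        "no_detection_fraction": 1.0 - float(df.detected.mean()) if len(df) else 0.0,
        "center_error_median_px": float(det.center_error_px.median()),
        "center_error_mean_px": float(det.center_error_px.mean()),
        "center_error_sd_px": float(det.center_error_px.std(ddof=0)),
        "iou_mean": float(det.iou.mean()),
        "direction_accuracy": float(det.direction_correct.mean()),
    }
    return df, agg


DEFAULT_SIZE_GRID = (500, 1000, 2500, 5000, 10000)


def subsample_benchmark(model_factory: Callable[[], object],
                        dataset: Sequence[TrainingSample],
                        sizes: Optional[Sequence[int]] = None,
                        hp: Hyperparams = None,
                        val_dataset: Sequence[TrainingSample] = (),
                        seed: int = 0) -> pd.DataFrame:
    """Train-from-scratch at nested training-set sizes, fixed validation.

    One shuffle (with ``seed``) is drawn; each size takes a prefix, so
    larger subsets contain the smaller ones.  ``sizes`` defaults to
    {500, 1000, 2500, 5000, 10000} clipped to availability.
    """
    if hp is None:
        hp = Hyperparams()
    if sizes is None:
        sizes = [s for s in DEFAULT_SIZE_GRID if s <= len(dataset)] \
            or [len(dataset)]
    sizes = sorted(int(s) for s in sizes)
    if sizes[-1] > len(dataset):
        raise ValueError("size exceeds dataset size")
    order = np.random.default_rng(seed).permutation(len(dataset))
    rows = []
    for size in sizes:
        subset = [dataset[i] for i in order[:size]]
        model = model_factory()
        train(model, subset, hp, val_dataset=val_dataset)
        _, agg = evaluate(model, val_dataset)
        rows.append({"size": size, **agg})
    return pd.DataFrame(rows)
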