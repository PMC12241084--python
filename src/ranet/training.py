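"""Training loop, evaluation and Monte-Carlo-dropout prediction.

The recipe: Adam, ReduceLROnPlateau on the validation loss, a maximum of
200 epochs with early stopping on the validation loss, and the hybrid
Dice/weighted-CE/boundary objective computed per slice and averaged over
the batch. The best-validation-loss parameters are retained.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .losses import LossWeights, _contour_dt, extract_contour, total_loss
from .metrics import MetricsReport, evaluate_masks
from .model import RaNet
from .nn import no_grad
from .optim import Adam, ReduceLROnPlateau


class DivergenceError(RuntimeError):
    """The training loss became non-finite."""


@dataclass
class TrainConfig:
    batch_size: int = 8
    learning_rate: float = 1e-3
    max_epochs: int = 200
    early_stopping_patience: int = 20
    scheduler_factor: float = 0.1
    scheduler_patience: int = 10
    min_lr: float = 1e-7
    max_steps: int | None = None  # optional cap on total optimiser steps
    threshold: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")


@dataclass
class TrainHistory:
    """Per-epoch traces plus the stopping record."""

    epochs: list[dict] = field(default_factory=list)
    stopped_epoch: int = -1
    stop_reason: str = ""
    best_epoch: int = -1
    best_val_loss: float = float("inf")

    def trace(self, key: str) -> list[float]:
        return [e[key] for e in self.epochs]

    def to_csv(self, path):
        path = Path(path)
        if not self.epochs:
            path.write_text("")
            return path
        keys = list(self.epochs[0])
        with path.open("w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=keys)
            writer.writeheader()
            writer.writerows(self.epochs)
        return path


def _as_batches(n: int, batch_size: int, order: np.ndarray):
    for start in range(0, n, batch_size):
        yield order[start:start + batch_size]


def _prepare(X, y):
    X = np.asarray(X, dtype=np.float32)
    y = np.asarray(y)
    if X.ndim != 3 or y.shape != X.shape:
        raise ValueError(f"expected matching (n, H, W) stacks, got "
                         f"{X.shape} and {y.shape}")
    if X.shape[1] % 8 or X.shape[2] % 8:
        raise ValueError("spatial sides must be divisible by 8")
    return X, (y > 0).astype(np.uint8)


def _batch_loss(prob: Tensor, masks: np.ndarray, weights: LossWeights,
                dts: list[np.ndarray | None]):
    """Per-slice hybrid loss averaged over the batch."""
    n = masks.shape[0]
    total = None
    sums: dict[str, float] = {}
    for i in range(n):
        p = ad.take_item(ad.take_item(prob, i), 0)  # (H, W)
        term, breakdown = total_loss(p, masks[i], weights,
                                     true_contour_dt=dts[i])
        total = term if total is None else total + term
        for k, v in breakdown.items():
            sums[k] = sums.get(k, 0.0) + v
    return total * (1.0 / n), {k: v / n for k, v in sums.items()}


def _forward_prob(model: RaNet, X: np.ndarray) -> Tensor:
    return model(Tensor(X[:, None]))["prob"]


def _validation_pass(model: RaNet, X, y, weights, dts, batch_size):
    model.eval()
    losses = []
    report = MetricsReport()
    with no_grad(model):
        for idx in _as_batches(len(X), batch_size, np.arange(len(X))):
            prob = _forward_prob(model, X[idx])
            loss, _ = _batch_loss(prob, y[idx], weights, [dts[i] for i in idx])
            losses.append(float(loss.data))
            pred = (prob.data[:, 0] >= 0.5).astype(np.uint8)
            for p, t in zip(pred, y[idx]):
                report.add(p, t)
    return float(np.mean(losses)), report.mean("dsc")


def _gt_distance_transforms(y: np.ndarray) -> list:
    dts = []
    for m in y:
        c = extract_contour(m)
        dts.append(_contour_dt(c, m.shape) if len(c) else None)
    return dts


def fit_model(model: RaNet, X, y, X_val, y_val,
              config: TrainConfig | None = None,
              weights: LossWeights | None = None) -> TrainHistory:
    """Train ``model`` in place; returns the history and leaves the model
    holding the best-validation-loss parameters."""
    config = config or TrainConfig()
    weights = weights or LossWeights()
    X, y = _prepare(X, y)
    X_val, y_val = _prepare(X_val, y_val)
    if len(X) == 0 or len(X_val) == 0:
        raise ValueError("train and validation sets must be nonempty")

    rng = np.random.default_rng(config.seed)
    for i, d in enumerate(model.dropout_modules()):
        d.reseed(config.seed * 1000 + i)
    opt = Adam(model.parameters(), lr=config.learning_rate)
    sched = ReduceLROnPlateau(opt, factor=config.scheduler_factor,
                              patience=config.scheduler_patience,
                              min_lr=config.min_lr)
    dts = _gt_distance_transforms(y)
    val_dts = _gt_distance_transforms(y_val)

    history = TrainHistory()
    best_state = None
    bad_epochs = 0
    steps = 0
    reason = "max_epochs"
    for epoch in range(config.max_epochs):
        model.train(True)
        order = rng.permutation(len(X))
        batch_losses, batch_terms = [], []
        hit_step_cap = False
        for idx in _as_batches(len(X), config.batch_size, order):
            prob = _forward_prob(model, X[idx])
            loss, terms = _batch_loss(prob, y[idx], weights,
                                      [dts[i] for i in idx])
            if not np.isfinite(loss.data):
                raise DivergenceError(f"non-finite training loss at epoch {epoch}")
            model.zero_grad()
            loss.backward()
            opt.step()
            steps += 1
            batch_losses.append(float(loss.data))
            batch_terms.append(terms)
            if config.max_steps is not None and steps >= config.max_steps:
                hit_step_cap = True
                break
        val_loss, val_dsc = _validation_pass(
            model, X_val, y_val, weights, val_dts, config.batch_size)
        record = {"epoch": epoch,
                  "train_loss": float(np.mean(batch_losses)),
                  "val_loss": val_loss, "val_dsc": val_dsc,
                  "lr": opt.lr, "steps": steps}
        for k in batch_terms[0]:
            record[f"train_{k}"] = float(np.mean([t[k] for t in batch_terms]))
        history.epochs.append(record)

        if val_loss < history.best_val_loss:
            history.best_val_loss = val_loss
            history.best_epoch = epoch
            best_state = model.state_dict()
            bad_epochs = 0
        else:
            bad_epochs += 1
        sched.step(val_loss)
        if bad_epochs >= config.early_stopping_patience:
            reason = "early_stopping"
            history.stopped_epoch = epoch
            break
        if hit_step_cap:
            reason = "max_steps"
            history.stopped_epoch = epoch
            break
        history.stopped_epoch = epoch
    history.stop_reason = reason
    if best_state is not None:
        model.load_state_dict(best_state)
    return history


def train(model: RaNet, datasets: dict, config: TrainConfig | None = None,
          weights: LossWeights | None = None,
          checkpoint_path=None) -> TrainHistory:
    """Train on phantom-pair splits ``{"train": [...], "val": [...]}``
    and optionally write the best checkpoint."""
    def unpack(pairs):
        X = np.stack([p.image.pixels for p in pairs])
        y = np.stack([p.mask.labels for p in pairs])
        return X, y

    if not datasets.get("train") or not datasets.get("val"):
        raise ValueError("datasets must provide nonempty 'train' and 'val'")
    Xt, yt = unpack(datasets["train"])
    Xv, yv = unpack(datasets["val"])
    history = fit_model(model, Xt, yt, Xv, yv, config, weights)
    if checkpoint_path is not None:
        model.save_checkpoint(checkpoint_path)
    return history


def evaluate(model: RaNet, X, y, *, threshold: float = 0.5,
             batch_size: int = 8) -> MetricsReport:
    """Deterministic evaluation (dropout off, running BN statistics)."""
    X, y = _prepare(X, y)
    model.eval()
    model.set_mc_dropout(False)
    preds = predict_masks(model, X, threshold=threshold, batch_size=batch_size)
    return evaluate_masks(list(preds), list(y))


def predict_masks(model: RaNet, X, *, threshold: float = 0.5,
                  batch_size: int = 8) -> np.ndarray:
    X = np.asarray(X, dtype=np.float32)
    if X.ndim == 2:
        X = X[None]
    model.eval()
    out = []
    with no_grad(model):
        for idx in _as_batches(len(X), batch_size, np.arange(len(X))):
            prob = _forward_prob(model, X[idx])
            out.append((prob.data[:, 0] >= threshold).astype(np.uint8))
    return np.concatenate(out)


def predict_proba(model: RaNet, X, *, batch_size: int = 8) -> np.ndarray:
    X = np.asarray(X, dtype=np.float32)
    if X.ndim == 2:
        X = X[None]
    model.eval()
    out = []
    with no_grad(model):
        for idx in _as_batches(len(X), batch_size, np.arange(len(X))):
            out.append(_forward_prob(model, X[idx]).data[:, 0])
    return np.concatenate(out)


def mc_dropout_predict(model: RaNet, image, T: int = 20, seed: int = 0):
    """T stochastic forward passes with dropout left active.

    Returns the per-pixel mean probability and (population) variance;
    batch norm keeps its running statistics throughout.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    img = np.asarray(image, dtype=np.float32)
    if img.ndim != 2:
        raise ValueError("mc_dropout_predict takes a single 2-D slice")
    model.eval()
    model.set_mc_dropout(True, seed=seed)
    try:
        with no_grad(model):
            samples = np.stack([
                _forward_prob(model, img[None]).data[0, 0] for _ in range(T)])
    finally:
        model.set_mc_dropout(False)
    mean = samples.mean(axis=0)
    var = samples.var(axis=0)
    # identical samples have exactly zero variance; np.var's rounded mean
    # would otherwise leave ~1e-32 residue
    var[np.all(samples == samples[0], axis=0)] = 0.0
    return mean, var
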