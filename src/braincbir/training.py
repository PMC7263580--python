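"""Supervised training of the descriptor network.

The network is trained as a disease classifier: descriptors are fed to the
softmax head, the cross-entropy between predicted class probabilities and the
annotated labels is minimized by backpropagation, and after several epochs
the trained weights double as the feature extractor for database
construction and retrieval.  Classification is used as the training task
because class-discriminative features transfer directly to similarity
search.

All shuffling and the stratified train/validation split derive from
``TrainConfig.seed``, so a fixed seed reproduces the loss trajectory exactly
on a fixed platform.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .nn.layers import Parameter
from .nn.network import MultiScaleNet, save_checkpoint

logger = logging.getLogger(__name__)

__all__ = ["TrainConfig", "TrainReport", "train", "cross_entropy", "Adam"]


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 20
    batch_size: int = 16
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    seed: int = 0
    val_fraction: float = 0.2
    label_smoothing: float = 0.1
    weight_decay: float = 1e-3

    def __post_init__(self) -> None:
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError("val_fraction must be in (0, 1)")
        if not 0.0 <= self.label_smoothing < 1.0:
            raise ValueError("label_smoothing must be in [0, 1)")
        if self.weight_decay < 0:
            raise ValueError("weight_decay must be >= 0")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")


@dataclass
class TrainReport:
    train_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    checkpoint_path: Path | None = None


def cross_entropy(
    logits: np.ndarray, labels: np.ndarray, label_smoothing: float = 0.0
) -> tuple[float, np.ndarray]:
    """Mean softmax cross-entropy and its gradient w.r.t. the logits.

    Uses the log-sum-exp form with the max subtracted, so large logits do
    not overflow.  With ``label_smoothing`` = s the target distribution is
    (1-s) on the annotated class and s/K elsewhere; besides regularising
    the classifier this is known to pull same-class penultimate features
    into tight clusters, which is what descriptor-based retrieval needs.
    """
    n, k = logits.shape
    z = logits.astype(np.float64)
    z -= z.max(axis=1, keepdims=True)
    logsumexp = np.log(np.exp(z).sum(axis=1))
    logp = z - logsumexp[:, None]
    target = np.full((n, k), label_smoothing / k)
    target[np.arange(n), labels] += 1.0 - label_smoothing
    loss = float(-(target * logp).sum(axis=1).mean())
    return loss, ((np.exp(logp) - target) / n).astype(np.float32)


class Adam:
    """Adam with bias-corrected moments and decoupled weight decay.

    The decay term matters for retrieval, not just regularisation: feature
    directions the classification loss never uses (e.g. ones encoding the
    imaging modality rather than the disease) receive no gradient, so
    without decay they survive and distort Euclidean distances between
    descriptors.  Decoupled decay shrinks them toward zero over training,
    leaving the descriptor dominated by class-informative directions.
    Biases are not decayed.
    """

    def __init__(
        self,
        params: list[Parameter],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
        weight_decay: float = 1e-3,
    ):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.wd = weight_decay
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * p.grad
            v *= self.b2
            v += (1.0 - self.b2) * np.square(p.grad)
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
            if self.wd and p.value.ndim > 1:  # decay weights, not biases
                p.value -= self.lr * self.wd * p.value


class _SGD:
    def __init__(self, params: list[Parameter], lr: float):
        self.params, self.lr = params, lr

    def step(self) -> None:
        for p in self.params:
            p.value -= self.lr * p.grad


def _stratified_split(
    labels: np.ndarray, val_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Per-class split; every class keeps at least one training image and,
    when it has two or more, at least one validation image."""
    train_idx, val_idx = [], []
    for cls in np.unique(labels):
        idx = rng.permutation(np.flatnonzero(labels == cls))
        n_val = int(round(val_fraction * idx.size))
        n_val = min(max(n_val, 1 if idx.size > 1 else 0), idx.size - 1)
        val_idx.append(idx[:n_val])
        train_idx.append(idx[n_val:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(val_idx))


def _accuracy(network: MultiScaleNet, x: np.ndarray, y: np.ndarray,
              batch_size: int) -> float:
    correct = 0
    for s in range(0, x.shape[0], batch_size):
        _, logits = network.forward(x[s : s + batch_size], train=False)
        correct += int((logits.argmax(axis=1) == y[s : s + batch_size]).sum())
    return correct / x.shape[0]


def train(
    network: MultiScaleNet,
    images,
    cfg: TrainConfig,
    checkpoint_path: str | Path | None = None,
) -> TrainReport:
    """Train ``network`` on labelled images by backpropagation.

    Raises
    ------
    ValueError
        If fewer than two classes are present or a label exceeds the
        network's class count.
    FloatingPointError
        If the loss becomes non-finite, reporting the epoch index.
    """
    images = list(images)
    labels = np.array([im.label for im in images], dtype=np.int64)
    if np.unique(labels).size < 2:
        raise ValueError("training requires at least two classes present")
    if labels.max() >= network.cfg.n_classes:
        raise ValueError(
            f"label {labels.max()} out of range for n_classes="
            f"{network.cfg.n_classes}"
        )
    x = np.stack([im.pixels for im in images]).astype(np.float32)[:, None]

    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    train_idx, val_idx = _stratified_split(labels, cfg.val_fraction, rng)
    x_tr, y_tr = x[train_idx], labels[train_idx]
    x_val, y_val = x[val_idx], labels[val_idx]

    params = network.parameters()
    opt = (
        Adam(params, lr=cfg.learning_rate, weight_decay=cfg.weight_decay)
        if cfg.optimizer == "adam"
        else _SGD(params, lr=cfg.learning_rate)
    )

    report = TrainReport()
    for epoch in range(cfg.epochs):
        order = rng.permutation(x_tr.shape[0])
        epoch_loss, n_seen = 0.0, 0
        for s in range(0, order.size, cfg.batch_size):
            sel = order[s : s + cfg.batch_size]
            xb, yb = x_tr[sel], y_tr[sel]
            network.zero_grad()
            _, logits = network.forward(xb, train=True)
            loss, dlogits = cross_entropy(logits, yb, cfg.label_smoothing)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}"
                )
            network.backward(dlogits)
            opt.step()
            epoch_loss += loss * xb.shape[0]
            n_seen += xb.shape[0]
        report.train_loss.append(epoch_loss / n_seen)
        report.val_accuracy.append(
            _accuracy(network, x_val, y_val, cfg.batch_size) if y_val.size else float("nan")
        )
        logger.info(
            "epoch %d/%d loss=%.4f val_acc=%.3f",
            epoch + 1, cfg.epochs, report.train_loss[-1], report.val_accuracy[-1],
        )

    if checkpoint_path is not None:
        report.checkpoint_path = save_checkpoint(network, checkpoint_path)
    return report


def write_training_log(report: TrainReport, path: str | Path) -> Path:
    """Per-epoch metrics as CSV (epoch, train_loss, val_accuracy)."""
    import pandas as pd

    path = Path(path)
    pd.DataFrame(
        {
            "epoch": np.arange(1, len(report.train_loss) + 1),
            "train_loss": report.train_loss,
            "val_accuracy": report.val_accuracy,
        }
    ).to_csv(path, index=False, float_format="%.6f")
    return path
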