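"""Training loop (Adam + focal loss + early stopping) and LOSO evaluation."""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..epochs import EpochSet
from .model import EEGNet, EEGNetConfig, build_model
from .ops import focal_loss_grad_logits

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1.25e-4
    beta1: float = 0.9
    beta2: float = 0.999
    batch_size: int = 128
    max_epochs: int = 300
    patience: int = 20  # early stop on validation loss, restore best weights
    focal_gamma: float = 2.0
    val_fraction: float = 0.2  # stratified split of training trials
    seed: int = 0
    dtype: str = "float64"  # "float32" halves CPU cost at training scale

    def __post_init__(self) -> None:
        if self.focal_gamma < 0:
            raise ValueError("focal_gamma must be >= 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class EvalMetrics:
    """Confusion counts with derived percentages (NaN where undefined)."""

    tp: int
    fn: int
    tn: int
    fp: int
    flags: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.tn + self.fp

    @property
    def accuracy(self) -> float:
        return 100.0 * (self.tp + self.tn) / self.n if self.n else float("nan")

    @property
    def sensitivity(self) -> float:
        pos = self.tp + self.fn
        return 100.0 * self.tp / pos if pos else float("nan")

    @property
    def specificity(self) -> float:
        neg = self.tn + self.fp
        return 100.0 * self.tn / neg if neg else float("nan")

    def as_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fn": self.fn,
            "tn": self.tn,
            "fp": self.fp,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        }


def confusion_metrics(predictions: np.ndarray, labels: np.ndarray) -> EvalMetrics:
    """Accuracy / sensitivity / specificity (in %) from binary predictions."""
    predictions = np.asarray(predictions, dtype=int)
    labels = np.asarray(labels, dtype=int)
    if len(predictions) != len(labels):
        raise ValueError("predictions/labels length mismatch")
    if len(labels) == 0:
        raise ValueError("empty input")
    tp = int(np.sum((predictions == 1) & (labels == 1)))
    fn = int(np.sum((predictions == 0) & (labels == 1)))
    tn = int(np.sum((predictions == 0) & (labels == 0)))
    fp = int(np.sum((predictions == 1) & (labels == 0)))
    m = EvalMetrics(tp=tp, fn=fn, tn=tn, fp=fp)
    if tp + fn == 0:
        m.flags.append("sensitivity undefined: no positive labels")
    if tn + fp == 0:
        m.flags.append("specificity undefined: no negative labels")
    return m


class Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float, beta1: float, beta2: float, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            params[k] -= self.lr * (self.m[k] / bc1) / (np.sqrt(self.v[k] / bc2) + self.eps)


def stratified_split(labels: np.ndarray, val_fraction: float, rng: np.random.Generator):
    """Seeded stratified train/val index split (each class split separately)."""
    train_idx, val_idx = [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        idx = rng.permutation(idx)
        n_val = max(1, int(round(val_fraction * len(idx))))
        val_idx.append(idx[:n_val])
        train_idx.append(idx[n_val:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(val_idx))


def train(
    model: EEGNet,
    train_set: EpochSet,
    val_set: EpochSet | None,
    tcfg: TrainConfig,
) -> tuple[EEGNet, pd.DataFrame]:
    """Fit *model* in place; returns it with a per-epoch history table.

    Early stopping monitors validation loss with ``tcfg.patience`` epochs of
    patience and restores the best weights. With ``max_epochs=0`` the model is
    returned untouched with an empty history.
    """
    for part, name in ((train_set, "training"), (val_set, "validation")):
        if part is not None and len(np.unique(part.labels)) < 2:
            raise ValueError(f"{name} set must contain both classes")
    rng = np.random.default_rng(tcfg.seed)
    opt = Adam(model.params, tcfg.learning_rate, tcfg.beta1, tcfg.beta2)
    x_tr, y_tr = train_set.data.astype(model.dtype), train_set.labels
    x_va = val_set.data.astype(model.dtype) if val_set is not None else None
    history: list[dict] = []
    best_loss, best_state, since_best = np.inf, None, 0
    for epoch in range(tcfg.max_epochs):
        order = rng.permutation(len(x_tr))
        losses, n_correct = [], 0
        for i in range(0, len(order), tcfg.batch_size):
            sel = order[i : i + tcfg.batch_size]
            logits, caches = model.forward(x_tr[sel], training=True, rng=rng)
            loss, dlogits = focal_loss_grad_logits(logits, y_tr[sel], tcfg.focal_gamma)
            grads, _ = model.backward(dlogits, caches)
            opt.step(model.params, grads)
            model.apply_max_norm()
            losses.append(loss)
            n_correct += int(np.sum(logits.argmax(axis=1) == y_tr[sel]))
        row = {
            "epoch": epoch,
            "train_loss": float(np.mean(losses)),
            "train_accuracy": 100.0 * n_correct / len(order),
        }
        if val_set is not None:
            logits, _ = model.forward(x_va, training=False)
            val_loss, _ = focal_loss_grad_logits(logits, val_set.labels, tcfg.focal_gamma)
            row["val_loss"] = val_loss
            row["val_accuracy"] = 100.0 * float(
                np.mean(logits.argmax(axis=1) == val_set.labels)
            )
            monitored = val_loss
        else:
            monitored = row["train_loss"]
        history.append(row)
        if monitored < best_loss:
            best_loss, since_best = monitored, 0
            best_state = {k: v.copy() for k, v in model.state_dict().items()}
        else:
            since_best += 1
            if since_best >= tcfg.patience:
                logger.info("early stop at epoch %d (best loss %.5f)", epoch, best_loss)
                break
    if best_state is not None:
        model.load_state_dict(best_state)
    return model, pd.DataFrame(history)


def train_on(
    dataset: EpochSet, cfg: EEGNetConfig, tcfg: TrainConfig
) -> tuple[EEGNet, pd.DataFrame]:
    """Build a model, carve a stratified validation split, and train."""
    model = build_model(cfg, seed=tcfg.seed, dtype=np.dtype(tcfg.dtype))
    if tcfg.val_fraction <= 0:
        return train(model, dataset, None, tcfg)
    rng = np.random.default_rng(tcfg.seed)
    tr_idx, va_idx = stratified_split(dataset.labels, tcfg.val_fraction, rng)
    return train(model, dataset.select(tr_idx), dataset.select(va_idx), tcfg)


def evaluate_loso(
    dataset: EpochSet,
    cfg: EEGNetConfig | None = None,
    tcfg: TrainConfig | None = None,
) -> tuple[pd.DataFrame, dict[int, EEGNet]]:
    """Leave-one-subject-out evaluation.

    For each subject: train one model on all other subjects' epochs (with a
    stratified validation split for early stopping) and test on the held-out
    subject, reporting metrics per session and scenario plus a pooled row.
    Returns (metrics table, {subject: trained model}).
    """
    cfg = cfg or EEGNetConfig()
    tcfg = tcfg or TrainConfig()
    subjects = np.unique(dataset.meta["subject"])
    if len(subjects) < 2:
        raise ValueError("LOSO needs at least 2 subjects")
    rows = []
    models: dict[int, EEGNet] = {}
    for subj in subjects:
        test_mask = (dataset.meta["subject"] == subj).to_numpy()
        if not test_mask.any():
            raise ValueError(f"subject {subj} has an empty test partition")
        train_pool = dataset.select(~test_mask)
        fold_tcfg = dataclasses.replace(tcfg, seed=tcfg.seed + int(subj))
        model, history = train_on(train_pool, cfg, fold_tcfg)
        model.history = history  # per-fold training curves, saved by the pipeline
        models[int(subj)] = model
        test_set = dataset.select(test_mask)
        preds = model.predict(test_set.data)
        groups = test_set.meta.groupby(["session", "scenario"]).indices
        for (session, scenario), idx in sorted(groups.items()):
            m = confusion_metrics(preds[idx], test_set.labels[idx])
            rows.append(
                {"subject": int(subj), "session": session, "scenario": scenario, **m.as_dict()}
            )
        pooled = confusion_metrics(preds, test_set.labels)
        rows.append(
            {"subject": int(subj), "session": 0, "scenario": "all", **pooled.as_dict()}
        )
    return pd.DataFrame(rows), models


def accuracy_table(metrics: pd.DataFrame, scenario: str) -> pd.DataFrame:
    """Subjects x sessions accuracy table with Mean and SD rows appended."""
    sub = metrics[(metrics["scenario"] == scenario) & (metrics["session"] > 0)]
    table = sub.pivot(index="subject", columns="session", values="accuracy")
    table.loc["Mean"] = table.mean(axis=0)
    table.loc["SD"] = table.iloc[:-1].std(axis=0, ddof=1)
    return table
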