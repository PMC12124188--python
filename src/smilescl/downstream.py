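"""Fine-tuning the pre-trained encoder on labeled molecular-property data.

Datasets are CSV-shaped: one SMILES column plus one column per task, with
empty cells marking missing labels (multi-task toxicology panels routinely
have them).  A single linear head sits on the encoder's pooled
representation; classification uses per-task binary cross-entropy averaged
over non-missing entries only, regression uses mean squared error on
standardized targets.  Early stopping monitors a validation metric and the
best weights are restored.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from ._autodiff import Tensor
from ._nn import AdamW, Linear, Module
from .chem import SmilesRecord, murcko_scaffold
from .encoder import SmilesEncoder

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# Data containers
# --------------------------------------------------------------------------

@dataclass
class LabeledDataset:
    """SMILES records with an (n, n_tasks) label matrix and missing-mask."""

    records: list[SmilesRecord]
    labels: np.ndarray          # (n, n_tasks), float; NaN where missing
    task_names: list[str]

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.float64)
        if self.labels.ndim == 1:
            self.labels = self.labels[:, None]
        if len(self.records) != self.labels.shape[0]:
            raise ValueError("records and labels disagree in length")
        if self.labels.shape[1] != len(self.task_names):
            raise ValueError("labels and task_names disagree in width")

    @property
    def missing_mask(self) -> np.ndarray:
        """True where a label is missing (never imputed)."""
        return np.isnan(self.labels)

    def __len__(self) -> int:
        return len(self.records)

    def subset(self, idx: Sequence[int]) -> "LabeledDataset":
        idx = np.asarray(idx)
        return LabeledDataset([self.records[i] for i in idx],
                              self.labels[idx], list(self.task_names))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame,
                       smiles_column: str = "smiles") -> "LabeledDataset":
        if smiles_column not in df.columns:
            raise ValueError(f"no {smiles_column!r} column in dataframe")
        task_names = [c for c in df.columns if c != smiles_column]
        if not task_names:
            raise ValueError("no label columns found")
        records = [SmilesRecord(smiles=s) for s in df[smiles_column]]
        labels = df[task_names].to_numpy(dtype=np.float64)
        return cls(records, labels, task_names)

    @classmethod
    def from_csv(cls, path: str | Path,
                 smiles_column: str = "smiles") -> "LabeledDataset":
        return cls.from_dataframe(pd.read_csv(path), smiles_column)


@dataclass
class TaskSpec:
    task_type: str              # "classification" | "regression"
    n_tasks: int
    metric: str                 # "auc_roc" | "rmse" | "mae"

    _COMPATIBLE = {"classification": {"auc_roc"},
                   "regression": {"rmse", "mae"}}

    def __post_init__(self):
        if self.task_type not in self._COMPATIBLE:
            raise ValueError(f"unknown task_type {self.task_type!r}")
        if self.metric not in self._COMPATIBLE[self.task_type]:
            raise ValueError(f"metric {self.metric!r} incompatible with "
                             f"{self.task_type}")
        if self.n_tasks <= 0:
            raise ValueError("n_tasks must be positive")


@dataclass
class FinetuneConfig:
    learning_rate: float = 1e-3
    epochs: int = 30
    batch_size: int = 32
    patience: int = 10
    freeze_encoder: bool = False
    representation: str = "pooled"
    seed: int = 0


# --------------------------------------------------------------------------
# Splits
# --------------------------------------------------------------------------

def split_dataset(dataset: LabeledDataset, method: str = "random",
                  fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
                  seed: int = 0,
                  ) -> tuple[LabeledDataset, LabeledDataset, LabeledDataset]:
    """Split into (train, valid, test) by seeded shuffle or by scaffold.

    The scaffold split groups molecules by their Bemis–Murcko scaffold and
    assigns whole groups, largest first, filling train, then valid, then
    test — structurally similar molecules never straddle splits.
    """
    if len(fractions) != 3 or any(f <= 0 for f in fractions) or \
            abs(sum(fractions) - 1.0) > 1e-6:
        raise ValueError("fractions must be three positives summing to 1")
    n = len(dataset)
    n_train = int(round(fractions[0] * n))
    n_valid = int(round(fractions[1] * n))
    if method == "random":
        order = np.random.default_rng(seed).permutation(n)
        parts = (order[:n_train], order[n_train:n_train + n_valid],
                 order[n_train + n_valid:])
    elif method == "scaffold":
        groups: dict[str, list[int]] = {}
        for i, rec in enumerate(dataset.records):
            groups.setdefault(murcko_scaffold(rec.smiles), []).append(i)
        ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))
        train, valid, test = [], [], []
        for _, idx in ordered:
            if len(train) + len(idx) <= n_train or not train:
                train.extend(idx)
            elif len(valid) + len(idx) <= n_valid or not valid:
                valid.extend(idx)
            else:
                test.extend(idx)
        parts = (np.array(train), np.array(valid), np.array(test))
    else:
        raise ValueError("method must be 'random' or 'scaffold'")
    names = ("train", "valid", "test")
    for name, p in zip(names, parts):
        if len(p) == 0:
            raise ValueError(f"{name} split received zero records")
    return tuple(dataset.subset(p) for p in parts)


# --------------------------------------------------------------------------
# Metrics
# --------------------------------------------------------------------------

def auc_roc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC-ROC: probability a random positive outscores a random negative,
    ties counted one half.  Requires both classes present."""
    labels = np.asarray(labels)
    scores = np.asarray(scores)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    if len(np.unique(labels[~np.isnan(labels)])) < 2:
        raise ValueError("AUC requires at least one positive and one negative")
    return float(roc_auc_score(labels, scores))


def rmse(pred: np.ndarray, truth: np.ndarray) -> float:
    pred, truth = np.asarray(pred), np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth must have equal length")
    return float(np.sqrt(np.mean((pred - truth) ** 2)))


def mae(pred: np.ndarray, truth: np.ndarray) -> float:
    pred, truth = np.asarray(pred), np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth must have equal length")
    return float(np.mean(np.abs(pred - truth)))


def multitask_metric(scores: np.ndarray, labels: np.ndarray,
                     metric: str) -> float:
    """Unweighted mean of the per-task metric over evaluable tasks.

    For AUC, tasks with a single observed class are excluded with a logged
    warning; missing labels (NaN) are dropped per task.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    labels = np.atleast_2d(np.asarray(labels, dtype=float))
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must share a shape")
    fns = {"auc_roc": auc_roc, "rmse": rmse, "mae": mae}
    fn = fns[metric]
    values = []
    for t in range(labels.shape[1]):
        obs = ~np.isnan(labels[:, t])
        y, s = labels[obs, t], scores[obs, t]
        if metric == "auc_roc" and len(np.unique(y)) < 2:
            logger.warning("task %d has a single observed class; "
                           "excluded from mean AUC", t)
            continue
        values.append(fn(s, y))
    if not values:
        raise ValueError("no evaluable task for the requested metric")
    return float(np.mean(values))


# --------------------------------------------------------------------------
# Fine-tuning
# --------------------------------------------------------------------------

def _masked_bce_loss(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Per-task binary cross-entropy averaged over non-missing entries.

    Stable formulation: BCE(l, y) = softplus(l) - y*l, with
    softplus(l) = max(l, 0) + log(1 + exp(-|l|)).
    """
    observed = ~np.isnan(labels)
    n_obs = observed.sum()
    if n_obs == 0:
        raise ValueError("batch contains no observed labels")
    y = np.where(observed, labels, 0.0)
    w = observed.astype(np.float64) / n_obs
    sp = _softplus(logits)
    per_entry = sp - logits * Tensor(y)
    return (per_entry * Tensor(w)).sum()


def _softplus(x: Tensor) -> Tensor:
    # log(1 + exp(x)) = max(x,0) + log(1 + exp(-|x|)); the max/abs pieces
    # are assembled with sign masks so gradients flow through x.
    pos = Tensor((x.data > 0).astype(np.float64))
    absx = x * pos - x * (1.0 - pos) * 1.0
    relu = x * pos
    return relu + (1.0 + (-1.0 * absx).exp()).log()


def _masked_mse_loss(pred: Tensor, targets: np.ndarray) -> Tensor:
    observed = ~np.isnan(targets)
    n_obs = observed.sum()
    if n_obs == 0:
        raise ValueError("batch contains no observed labels")
    y = np.where(observed, targets, 0.0)
    w = observed.astype(np.float64) / n_obs
    diff = pred - Tensor(y)
    return (diff * diff * Tensor(w)).sum()


class FinetunedModel(Module):
    """Encoder + linear task head, with target (de)standardization."""

    def __init__(self, encoder: SmilesEncoder, task_spec: TaskSpec,
                 config: FinetuneConfig, head_rng: np.random.Generator):
        self.encoder = encoder
        self.task_spec = task_spec
        self.config = config
        d = (encoder.config.projection_dim
             if config.representation == "projected"
             else encoder.config.d_model)
        self.head = Linear(d, task_spec.n_tasks, head_rng)
        self.target_mean = np.zeros(task_spec.n_tasks)
        self.target_std = np.ones(task_spec.n_tasks)

    def named_parameters(self, prefix: str = ""):
        yield from self.head.named_parameters(prefix=prefix + "head.")
        if not self.config.freeze_encoder:
            yield from self.encoder.named_parameters(prefix=prefix + "encoder.")

    def _forward(self, records: Sequence[SmilesRecord], rng=None,
                 training=False) -> Tensor:
        from .tokenizer import encode
        seqs = [encode(self.encoder.vocab, r.smiles,
                       self.encoder.config.max_len) for r in records]
        ids = np.stack([s.ids for s in seqs])
        lengths = np.array([s.true_length for s in seqs])
        pooled, projected = self.encoder.forward(ids, lengths, rng=rng,
                                                 training=training)
        rep = projected if self.config.representation == "projected" else pooled
        return self.head(rep)

    def predict(self, records: Sequence[SmilesRecord],
                batch_size: int = 64) -> np.ndarray:
        """Scores (logits) for classification, destandardized values for
        regression; shape (n, n_tasks)."""
        outs = []
        for i in range(0, len(records), batch_size):
            out = self._forward(records[i:i + batch_size]).data
            outs.append(out)
        pred = np.concatenate(outs, axis=0)
        if self.task_spec.task_type == "regression":
            pred = pred * self.target_std + self.target_mean
        return pred

    def evaluate(self, dataset: LabeledDataset) -> dict:
        pred = self.predict(dataset.records)
        mean = multitask_metric(pred, dataset.labels, self.task_spec.metric)
        return {"metric": self.task_spec.metric, "mean": mean}


def finetune(encoder: SmilesEncoder, splits, task_spec: TaskSpec,
             config: FinetuneConfig | None = None) -> FinetunedModel:
    """Fine-tune ``encoder`` with a single linear head.

    ``splits`` is the (train, valid, test) triple from
    :func:`split_dataset`; only train and valid are used here.  The
    encoder is updated jointly with the head unless
    ``config.freeze_encoder``.  Early stopping: the validation metric is
    checked every epoch; after ``patience`` checks without improvement,
    training stops and the best weights are restored.
    """
    config = config or FinetuneConfig()
    encoder = encoder.clone()  # never mutate the caller's checkpoint
    train, valid = splits[0], splits[1]
    if train.labels.shape[1] != task_spec.n_tasks:
        raise ValueError("dataset width disagrees with task_spec.n_tasks")
    all_missing = np.all(np.isnan(train.labels), axis=0)
    if all_missing.any():
        bad = [train.task_names[i] for i in np.where(all_missing)[0]]
        raise ValueError(f"task(s) with no observed labels: {bad}")
    master = np.random.SeedSequence(config.seed)
    head_ss, shuffle_ss, dropout_ss = master.spawn(3)
    model = FinetunedModel(encoder, task_spec, config,
                           np.random.default_rng(head_ss))
    if task_spec.task_type == "regression":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            model.target_mean = np.nanmean(train.labels, axis=0)
            std = np.nanstd(train.labels, axis=0)
        model.target_std = np.where(std > 0, std, 1.0)
    shuffle_rng = np.random.default_rng(shuffle_ss)
    dropout_rng = np.random.default_rng(dropout_ss)
    opt = AdamW(model.parameters(), lr=config.learning_rate)
    higher_is_better = task_spec.metric == "auc_roc"
    best_score, best_state, stale = None, None, 0
    for epoch in range(config.epochs):
        order = shuffle_rng.permutation(len(train))
        for i in range(0, len(order), config.batch_size):
            idx = order[i:i + config.batch_size]
            if len(idx) < 2:
                continue
            recs = [train.records[j] for j in idx]
            labels = train.labels[idx]
            if np.all(np.isnan(labels)):
                continue
            out = model._forward(recs, rng=dropout_rng, training=True)
            if task_spec.task_type == "classification":
                loss = _masked_bce_loss(out, labels)
            else:
                z = (labels - model.target_mean) / model.target_std
                loss = _masked_mse_loss(out, z)
            opt.zero_grad()
            loss.backward()
            opt.step()
        score = model.evaluate(valid)["mean"]
        improved = (best_score is None or
                    (score > best_score if higher_is_better
                     else score < best_score))
        if improved:
            best_score, best_state, stale = score, model.state_dict(), 0
        else:
            stale += 1
            if stale >= config.patience:
                break
    if best_state is not None:
        model.load_state_dict(best_state)
    return model
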