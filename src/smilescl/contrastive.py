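"""Contrastive pre-training: pair assembly, NT-Xent loss, training loop.

Each mini-batch holds N distinct molecules.  The anchor view is the
original SMILES; the positive view is either a randomized rewriting of the
same molecule (atom-shuffled SMILES) or a partially masked copy of the
string.  All 2N projected embeddings are stacked and the symmetric
normalized temperature-scaled cross-entropy (NT-Xent) loss is applied:
every view is an anchor once, its positive is the other view of the same
molecule, and the remaining 2N-2 views are in-batch negatives.
"""

from __future__ import annotations

import csv
import json
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from ._autodiff import Tensor, concat
from ._nn import AdamW
from .chem import SmilesRecord, enumerate_randomized, mask_augment
from .encoder import EncoderConfig, SmilesEncoder
from .tokenizer import BpeVocabulary, TokenSequence, encode, train_bpe


@dataclass
class PretrainConfig:
    """Pre-training hyperparameters (defaults: full-scale study settings)."""

    batch_size: int = 128
    temperature: float = 0.2
    learning_rate: float = 1e-4
    epochs: int = 16
    optimizer: str = "AdamW"
    augmentation: str = "randomized"
    mask_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.batch_size < 2:
            raise ValueError("batch_size must be >= 2 (negatives required)")
        if self.augmentation not in ("randomized", "masked"):
            raise ValueError("augmentation must be 'randomized' or 'masked'")
        if self.optimizer != "AdamW":
            raise ValueError("only the AdamW optimizer is supported")


@dataclass
class ContrastiveBatch:
    """Index-aligned anchor/positive token sequences for N molecules."""

    anchors: list[TokenSequence]
    positives: list[TokenSequence]

    def __post_init__(self):
        if len(self.anchors) != len(self.positives):
            raise ValueError("anchors and positives must be index-aligned")


@dataclass
class TrainingLog:
    """Per-epoch loss trajectory plus the pre-update (epoch 0) loss."""

    initial_loss: float | None = None
    epochs: list[dict] = field(default_factory=list)

    @property
    def losses(self) -> list[float]:
        return [e["mean_loss"] for e in self.epochs]

    def to_csv(self, path: str | Path) -> None:
        with Path(path).open("w", newline="") as fh:
            writer = csv.DictWriter(
                fh, fieldnames=["epoch", "mean_loss", "lr", "wall_time"])
            writer.writeheader()
            for row in self.epochs:
                writer.writerow(row)

    def to_jsonl(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            if self.initial_loss is not None:
                fh.write(json.dumps({"event": "initial_eval",
                                     "mean_loss": self.initial_loss}) + "\n")
            for row in self.epochs:
                fh.write(json.dumps({"event": "epoch", **row}) + "\n")


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine of the angle between two vectors: A.B / (|A||B|), in [-1, 1].

    Symmetric and invariant to positive rescaling of either argument.
    Raises on zero vectors, where the similarity is undefined.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("cosine similarity is undefined for a zero vector")
    return float(np.clip(a @ b / (na * nb), -1.0, 1.0))


def _nt_xent_stacked(A: Tensor, N: int, temperature: float) -> Tensor:
    """Differentiable symmetric NT-Xent over a stacked (2N, d) tensor whose
    first N rows are anchors and last N rows their index-aligned positives."""
    if N < 2:
        raise ValueError("NT-Xent requires N >= 2 (at least one negative)")
    if A.shape[0] != 2 * N:
        raise ValueError(f"expected 2N={2 * N} stacked rows, got {A.shape[0]}")
    norms = (A * A).sum(axis=1, keepdims=True).sqrt()
    An = A / norms
    S = (An @ An.transpose(1, 0)) * (1.0 / temperature)  # (2N, 2N)
    M = S + Tensor(np.diag(np.full(2 * N, -1e9)))        # exclude self
    shift = Tensor(M.data.max(axis=1, keepdims=True))
    lse = ((M - shift).exp().sum(axis=1, keepdims=True)).log() + shift
    pos_index = np.concatenate([np.arange(N) + N, np.arange(N)])
    P = np.zeros((2 * N, 2 * N))
    P[np.arange(2 * N), pos_index] = 1.0
    pos = (M * Tensor(P)).sum(axis=1, keepdims=True)
    return (lse - pos).mean()


def _nt_xent_tensor(Z: Tensor, Z_aug: Tensor, temperature: float) -> Tensor:
    """Differentiable symmetric NT-Xent for two aligned (N, d) tensors."""
    if Z.shape != Z_aug.shape:
        raise ValueError("embedding sets must be index-aligned and same shape")
    return _nt_xent_stacked(concat([Z, Z_aug], axis=0), Z.shape[0], temperature)


def nt_xent_loss(Z, Z_aug, temperature: float = 0.2) -> float:
    """Symmetric in-batch NT-Xent loss value for two aligned embedding sets.

    With all 2N embeddings identical (or in the infinite-temperature limit)
    the softmax over the 2N-1 candidates is uniform and the loss equals
    ln(2N-1).
    """
    Zt = Z if isinstance(Z, Tensor) else Tensor(np.asarray(Z, dtype=np.float64))
    Zat = Z_aug if isinstance(Z_aug, Tensor) else Tensor(
        np.asarray(Z_aug, dtype=np.float64))
    out = _nt_xent_tensor(Zt, Zat, temperature)
    if isinstance(Z, Tensor) or isinstance(Z_aug, Tensor):
        return out
    return out.item()


def make_batch(records: Sequence[SmilesRecord], vocab: BpeVocabulary,
               config: PretrainConfig, max_len: int, epoch: int = 0,
               batch_index: int = 0) -> ContrastiveBatch:
    """Assemble anchor/positive token sequences for N distinct molecules.

    Duplicate molecules (by canonical form) are rejected: two views of the
    same molecule in different pair slots would be treated as negatives.
    Augmentation seeds derive from (config.seed, epoch, batch_index, slot),
    so batches are reproducible.
    """
    canonicals = [r.with_canonical().canonical for r in records]
    if len(set(canonicals)) != len(canonicals):
        raise ValueError("duplicate canonical SMILES within a batch "
                         "(would create false negatives)")
    ss = np.random.SeedSequence(
        entropy=(config.seed, 1000 + epoch, batch_index))
    seeds = ss.generate_state(len(records))
    anchors, positives = [], []
    for rec, s in zip(records, seeds):
        s = int(s) % (2 ** 31)
        if config.augmentation == "randomized":
            view = enumerate_randomized(rec.smiles, seed=s)
        else:
            view = mask_augment(rec.smiles, config.mask_fraction, seed=s)
        anchors.append(encode(vocab, rec.smiles, max_len))
        positives.append(encode(vocab, view, max_len))
    return ContrastiveBatch(anchors=anchors, positives=positives)


def _batch_loss(model: SmilesEncoder, batch: ContrastiveBatch,
                temperature: float, rng=None, training=False) -> Tensor:
    seqs = batch.anchors + batch.positives
    ids = np.stack([s.ids for s in seqs])
    lengths = np.array([s.true_length for s in seqs])
    _, projected = model.forward(ids, lengths, rng=rng, training=training)
    return _nt_xent_stacked(projected, len(batch.anchors), temperature)


def pretrain(corpus: Sequence[SmilesRecord], encoder_config: EncoderConfig,
             pretrain_config: PretrainConfig,
             vocab: BpeVocabulary | None = None,
             ) -> tuple[SmilesEncoder, TrainingLog]:
    """Run the contrastive pre-training loop on a SMILES corpus.

    Trains a BPE vocabulary on the corpus if none is supplied, evaluates
    the mean loss once before any update (logged as ``initial_loss``), then
    runs ``epochs`` passes of shuffled mini-batches (last incomplete batch
    dropped) with AdamW updates.  One master seed fans out to independent
    streams for initialization, shuffling, augmentation and dropout.
    Returns the trained model (vocabulary attached, training metadata
    recorded) and the loss log.
    """
    N = pretrain_config.batch_size
    if len(corpus) < N:
        raise ValueError(f"corpus of {len(corpus)} molecules is smaller than "
                         f"one batch (N={N})")
    if vocab is None:
        vocab = train_bpe(corpus, vocab_size=encoder_config.vocab_size)
    master = np.random.SeedSequence(pretrain_config.seed)
    init_ss, shuffle_ss, dropout_ss = master.spawn(3)
    # one master seed fans out: initialization, shuffling, dropout
    # (augmentation streams derive from (seed, epoch, batch) in make_batch)
    init_seed = int(init_ss.generate_state(1)[0]) % (2 ** 31)
    model = SmilesEncoder(replace(encoder_config, seed=init_seed), vocab=vocab)
    opt = AdamW(model.parameters(), lr=pretrain_config.learning_rate)
    shuffle_rng = np.random.default_rng(shuffle_ss)
    dropout_rng = np.random.default_rng(dropout_ss)
    n_batches = len(corpus) // N
    log = TrainingLog()

    def batches(epoch: int, order: np.ndarray):
        for b in range(n_batches):
            idx = order[b * N:(b + 1) * N]
            recs = [corpus[i] for i in idx]
            yield b, make_batch(recs, vocab, pretrain_config,
                                max_len=encoder_config.max_len,
                                epoch=epoch, batch_index=b)

    # pre-update evaluation pass ("epoch 0" loss at random initialization)
    init_losses = []
    for _, batch in batches(0, np.arange(len(corpus))):
        init_losses.append(
            _batch_loss(model, batch, pretrain_config.temperature).item())
    log.initial_loss = float(np.mean(init_losses))

    for epoch in range(1, pretrain_config.epochs + 1):
        t0 = time.perf_counter()
        order = shuffle_rng.permutation(len(corpus))
        losses = []
        for _, batch in batches(epoch, order):
            loss = _batch_loss(model, batch, pretrain_config.temperature,
                               rng=dropout_rng, training=True)
            value = loss.item()
            if not np.isfinite(value):
                raise FloatingPointError(
                    f"non-finite loss {value} at epoch {epoch}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(value)
        log.epochs.append({
            "epoch": epoch,
            "mean_loss": float(np.mean(losses)),
            "lr": pretrain_config.learning_rate,
            "wall_time": time.perf_counter() - t0,
        })
    model.training_meta = {
        "epochs": pretrain_config.epochs,
        "seed": pretrain_config.seed,
        "initial_loss": log.initial_loss,
        "loss_history": log.losses,
        "pretrain_config": asdict(pretrain_config),
    }
    return model, log
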