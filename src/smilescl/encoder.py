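"""Transformer SMILES encoder: tokens -> one fixed-width embedding.

Pipeline per sequence: token embedding (scaled by sqrt(d_model)) + fixed
sinusoidal positional encoding -> pre-norm self-attention blocks (PAD keys
masked out) -> final layer norm -> global average pooling over non-pad
positions -> linear projection.  Two representations are exposed for each
input: the pooled pre-projection vector ("pooled", the downstream default)
and the projected vector ("projected", used by the contrastive loss).
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from ._autodiff import Tensor
from ._nn import (EncoderBlock, EmbeddingTable, LayerNorm, Linear, Module,
                  NEG_INF, dropout, sinusoidal_positions)
from .tokenizer import BpeVocabulary, TokenSequence, encode

REPRESENTATIONS = ("pooled", "projected")


@dataclass
class EncoderConfig:
    """Architecture hyperparameters.

    Defaults follow the full-scale configuration (width 768, 2 layers,
    8 heads, 512-token context, 300-token vocabulary); desk-scale studies
    shrink ``d_model`` and ``max_len``.
    """

    d_model: int = 768
    n_layers: int = 2
    n_heads: int = 8
    max_len: int = 512
    vocab_size: int = 300
    projection_dim: int | None = None
    dropout: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.projection_dim is None:
            self.projection_dim = self.d_model
        for name in ("d_model", "n_layers", "n_heads", "max_len",
                     "vocab_size", "projection_dim"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.d_model % self.n_heads != 0:
            raise ValueError(
                f"d_model ({self.d_model}) must be divisible by "
                f"n_heads ({self.n_heads})"
            )
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")


@dataclass
class Embedding:
    """One fixed-width embedding vector for one source sequence."""

    vector: np.ndarray
    source_id: str | None = None

    def __post_init__(self):
        self.vector = np.asarray(self.vector, dtype=np.float64)
        if not np.all(np.isfinite(self.vector)):
            raise ValueError("embedding contains non-finite entries")


class VocabularyMismatchError(ValueError):
    pass


class SmilesEncoder(Module):
    """The encoder model handle.

    Holds the architecture, its parameters and (optionally) the vocabulary
    it was trained with; carries training metadata into checkpoints.
    """

    def __init__(self, config: EncoderConfig, vocab: BpeVocabulary | None = None):
        self.config = config
        self.vocab = vocab
        if vocab is not None and vocab.size != config.vocab_size:
            raise VocabularyMismatchError(
                f"vocabulary size {vocab.size} != config.vocab_size "
                f"{config.vocab_size}"
            )
        rng = np.random.default_rng(config.seed)
        d = config.d_model
        self.token_embedding = EmbeddingTable(config.vocab_size, d, rng)
        self.blocks = [EncoderBlock(d, config.n_heads, rng, config.dropout)
                       for _ in range(config.n_layers)]
        self.final_norm = LayerNorm(d)
        self.projection = Linear(d, config.projection_dim, rng)
        self._pos = sinusoidal_positions(config.max_len, d)
        self.training_meta: dict = {"epochs": 0, "seed": config.seed,
                                    "loss_history": []}

    # -- forward ------------------------------------------------------------
    def forward(self, ids: np.ndarray, lengths: np.ndarray,
                rng: np.random.Generator | None = None,
                training: bool = False) -> tuple[Tensor, Tensor]:
        """Run a batch; returns (pooled, projected) Tensors.

        ``ids``: (B, L) int array padded with 0; ``lengths``: (B,) true
        lengths.  Attention never attends to PAD keys and the pooling mean
        runs over non-pad positions only, so PAD content cannot leak into
        the outputs.
        """
        ids = np.asarray(ids)
        lengths = np.asarray(lengths)
        B, L = ids.shape
        if L != self.config.max_len:
            raise ValueError(f"expected sequences of length "
                             f"{self.config.max_len}, got {L}")
        # Trailing all-PAD columns contribute exact zeros everywhere (masked
        # attention keys, zero pooling weight), so computation is trimmed to
        # the longest true sequence in the batch without changing any output.
        L = max(int(lengths.max()), 1)
        ids = ids[:, :L]
        d = self.config.d_model
        x = self.token_embedding(ids) * (d ** 0.5) + Tensor(self._pos[None, :L])
        x = dropout(x, self.config.dropout, rng, training)
        valid = np.arange(L)[None, :] < lengths[:, None]       # (B, L)
        key_bias = np.where(valid, 0.0, NEG_INF)[:, None, None, :]
        for block in self.blocks:
            x = block(x, key_bias, rng=rng, training=training)
        x = self.final_norm(x)
        # masked global average pooling
        w = (valid.astype(np.float64) / lengths[:, None])[:, :, None]
        pooled = (x * Tensor(w)).sum(axis=1)                   # (B, d)
        projected = self.projection(pooled)
        return pooled, projected

    # -- inference API -------------------------------------------------------
    def embed_batch(self, sequences: Sequence[TokenSequence],
                    representation: str = "pooled",
                    source_ids: Sequence[str] | None = None) -> list[Embedding]:
        """Embed already-tokenized sequences (eval mode, no dropout)."""
        if not sequences:
            raise ValueError("batch is empty")
        if representation not in REPRESENTATIONS:
            raise ValueError(f"representation must be one of {REPRESENTATIONS}")
        ids = np.stack([s.ids for s in sequences])
        lengths = np.array([s.true_length for s in sequences])
        pooled, projected = self.forward(ids, lengths, training=False)
        out = projected if representation == "projected" else pooled
        vecs = out.data
        if source_ids is None:
            source_ids = [None] * len(sequences)
        return [Embedding(vector=v, source_id=sid)
                for v, sid in zip(vecs, source_ids)]

    def embed_smiles(self, smiles_list: Sequence[str],
                     representation: str = "pooled",
                     batch_size: int = 64) -> np.ndarray:
        """Tokenize and embed raw SMILES strings; returns (n, dim) array."""
        if self.vocab is None:
            raise VocabularyMismatchError("encoder has no attached vocabulary")
        seqs = [encode(self.vocab, s, self.config.max_len)
                for s in smiles_list]
        chunks = []
        for i in range(0, len(seqs), batch_size):
            chunk = self.embed_batch(seqs[i:i + batch_size], representation)
            chunks.append(np.stack([e.vector for e in chunk]))
        return np.concatenate(chunks, axis=0)

    def clone(self) -> "SmilesEncoder":
        """Deep copy (fresh parameter arrays, same config/vocab/metadata)."""
        other = SmilesEncoder(self.config, vocab=self.vocab)
        other.load_state_dict(self.state_dict())
        other.training_meta = dict(self.training_meta)
        return other

    # -- checkpointing -------------------------------------------------------
    def save_checkpoint(self, path: str | Path) -> None:
        """Write weights (``.npz``) plus a JSON sidecar (config, vocabulary,
        fingerprint, training metadata) at ``path`` + ``.json``."""
        path = Path(path)
        with open(str(path) + ".npz", "wb") as fh:
            np.savez(fh, **self.state_dict())
        sidecar = {
            "encoder_config": asdict(self.config),
            "vocab_fingerprint": (self.vocab.fingerprint()
                                  if self.vocab else None),
            "vocab": (json.loads(self.vocab.to_json())
                      if self.vocab else None),
            "training_meta": self.training_meta,
        }
        Path(str(path) + ".json").write_text(
            json.dumps(sidecar, sort_keys=True, indent=1), encoding="utf-8")

    @classmethod
    def load_checkpoint(cls, path: str | Path,
                        vocab: BpeVocabulary | None = None) -> "SmilesEncoder":
        """Reload a checkpoint; verifies the stored vocabulary fingerprint
        (and, if ``vocab`` is given, that it matches the checkpoint's)."""
        path = Path(path)
        weights_path = Path(str(path) + ".npz")
        sidecar = json.loads(Path(str(path) + ".json").read_text())
        config = EncoderConfig(**sidecar["encoder_config"])
        stored_vocab = None
        if sidecar["vocab"] is not None:
            stored_vocab = BpeVocabulary.from_json(json.dumps(sidecar["vocab"]))
            if stored_vocab.fingerprint() != sidecar["vocab_fingerprint"]:
                raise VocabularyMismatchError(
                    "checkpoint vocabulary fingerprint does not match its "
                    "stored vocabulary"
                )
        if vocab is not None:
            if sidecar["vocab_fingerprint"] != vocab.fingerprint():
                raise VocabularyMismatchError(
                    "provided vocabulary does not match checkpoint fingerprint"
                )
            stored_vocab = vocab
        model = cls(config, vocab=stored_vocab)
        with np.load(weights_path) as npz:
            model.load_state_dict({k: npz[k] for k in npz.files})
        model.training_meta = sidecar["training_meta"]
        return model


def build_encoder(config: EncoderConfig,
                  vocab: BpeVocabulary | None = None) -> SmilesEncoder:
    """Construct a freshly initialized encoder (seed taken from config)."""
    return SmilesEncoder(config, vocab=vocab)


def parameter_count(model: SmilesEncoder) -> int:
    return sum(p.data.size for p in model.parameters())
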