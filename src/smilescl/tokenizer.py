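"""Byte-pair-encoding tokenizer for SMILES with fixed-length padding.

Training starts from the character alphabet of the corpus and repeatedly
merges the most frequent adjacent symbol pair until the vocabulary budget
(default 300, special tokens included) is reached.  Ties are broken by the
lexicographically smallest pair so retraining is reproducible across runs
and platforms.  Encoding applies the merges greedily in training order and
zero-pads to a fixed maximum length (default 512); sequences that do not
fit raise instead of being truncated.
"""

from __future__ import annotations

import hashlib
import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .chem import MASK_CHAR, SmilesRecord

DEFAULT_VOCAB_SIZE = 300
DEFAULT_MAX_LEN = 512

PAD_TOKEN = "<pad>"
UNK_TOKEN = "<unk>"
MASK_TOKEN = "<mask>"
_SPECIALS = (PAD_TOKEN, UNK_TOKEN, MASK_TOKEN)

VOCAB_FORMAT_VERSION = 1


class VocabularyError(ValueError):
    pass


class SequenceOverflowError(ValueError):
    """Tokenized sequence longer than the configured maximum length."""


@dataclass
class BpeVocabulary:
    """Ordered merge rules plus the token<->id mapping.

    ``special_tokens`` maps the PAD/UNK/MASK token strings to their ids;
    PAD is always id 0 so that zero-padding and "pad id" coincide.
    """

    merges: list[tuple[str, str]]
    token_to_id: dict[str, int]
    special_tokens: dict[str, int]

    def __post_init__(self):
        if self.special_tokens.get(PAD_TOKEN) != 0:
            raise VocabularyError("PAD token must have id 0")
        ids = sorted(self.token_to_id.values())
        if ids != list(range(len(ids))):
            raise VocabularyError("token ids must be dense in [0, size)")

    @property
    def size(self) -> int:
        return len(self.token_to_id)

    @property
    def pad_id(self) -> int:
        return self.special_tokens[PAD_TOKEN]

    @property
    def unk_id(self) -> int:
        return self.special_tokens[UNK_TOKEN]

    @property
    def mask_id(self) -> int:
        return self.special_tokens[MASK_TOKEN]

    @property
    def id_to_token(self) -> dict[int, str]:
        return {i: t for t, i in self.token_to_id.items()}

    # -- serialization ------------------------------------------------------
    def to_json(self) -> str:
        payload = {
            "version": VOCAB_FORMAT_VERSION,
            "merges": [list(m) for m in self.merges],
            "token_to_id": self.token_to_id,
            "special_tokens": self.special_tokens,
        }
        return json.dumps(payload, sort_keys=True, separators=(",", ":"))

    def fingerprint(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n", encoding="utf-8")

    @classmethod
    def from_json(cls, text: str) -> "BpeVocabulary":
        try:
            payload = json.loads(text)
        except json.JSONDecodeError as e:
            raise VocabularyError(f"malformed vocabulary file: {e}") from e
        for key in ("merges", "token_to_id", "special_tokens"):
            if key not in payload:
                raise VocabularyError(f"vocabulary file missing key {key!r}")
        specials = payload["special_tokens"]
        for tok in _SPECIALS:
            if tok not in specials:
                raise VocabularyError(f"vocabulary missing special token {tok!r}")
        return cls(merges=[tuple(m) for m in payload["merges"]],
                   token_to_id=dict(payload["token_to_id"]),
                   special_tokens=dict(specials))

    @classmethod
    def load(cls, path: str | Path) -> "BpeVocabulary":
        return cls.from_json(Path(path).read_text(encoding="utf-8"))


@dataclass
class TokenSequence:
    """Fixed-length id sequence with its true (un-padded) length."""

    ids: np.ndarray
    true_length: int

    @property
    def mask(self) -> np.ndarray:
        m = np.zeros(len(self.ids), dtype=bool)
        m[: self.true_length] = True
        return m


def _as_strings(corpus: Iterable) -> list[str]:
    out = []
    for item in corpus:
        out.append(item.smiles if isinstance(item, SmilesRecord) else str(item))
    return out


def train_bpe(corpus: Sequence, vocab_size: int = DEFAULT_VOCAB_SIZE,
              ) -> BpeVocabulary:
    """Learn a BPE vocabulary of exactly ``vocab_size`` tokens.

    The budget counts the three special tokens.  Merging is deterministic:
    the most frequent adjacent pair wins, ties go to the lexicographically
    smallest ``(left, right)`` pair.  Raises if the budget is smaller than
    alphabet + specials, or if the corpus is too small to support enough
    merges.
    """
    strings = _as_strings(corpus)
    if not strings:
        raise ValueError("corpus is empty")
    alphabet = sorted(set("".join(strings)) - {MASK_CHAR})
    n_specials = len(_SPECIALS)
    if vocab_size < len(alphabet) + n_specials:
        raise VocabularyError(
            f"vocab_size={vocab_size} smaller than alphabet "
            f"({len(alphabet)}) + specials ({n_specials})"
        )
    tokens = [PAD_TOKEN, UNK_TOKEN, MASK_TOKEN] + alphabet
    work = [list(s) for s in strings]
    merges: list[tuple[str, str]] = []
    while len(tokens) < vocab_size:
        counts: Counter = Counter()
        for seq in work:
            for a, b in zip(seq, seq[1:]):
                counts[(a, b)] += 1
        if not counts:
            raise VocabularyError(
                f"corpus exhausted after {len(merges)} merges; cannot reach "
                f"vocab_size={vocab_size}"
            )
        best = min(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0]
        merges.append(best)
        merged = best[0] + best[1]
        tokens.append(merged)
        a, b = best
        for si, seq in enumerate(work):
            if a not in seq:
                continue
            out, i, n = [], 0, len(seq)
            while i < n:
                if i + 1 < n and seq[i] == a and seq[i + 1] == b:
                    out.append(merged)
                    i += 2
                else:
                    out.append(seq[i])
                    i += 1
            work[si] = out
    token_to_id = {t: i for i, t in enumerate(tokens)}
    specials = {t: token_to_id[t] for t in _SPECIALS}
    return BpeVocabulary(merges=merges, token_to_id=token_to_id,
                         special_tokens=specials)


def tokenize(vocab: BpeVocabulary, smiles: str) -> list[str]:
    """Split a string into vocabulary tokens (merges in training order)."""
    seq = [MASK_TOKEN if c == MASK_CHAR else c for c in smiles]
    for a, b in vocab.merges:
        if a not in seq:
            continue
        merged = a + b
        out, i, n = [], 0, len(seq)
        while i < n:
            if i + 1 < n and seq[i] == a and seq[i + 1] == b:
                out.append(merged)
                i += 2
            else:
                out.append(seq[i])
                i += 1
        seq = out
    return seq


def encode(vocab: BpeVocabulary, smiles: str,
           max_len: int = DEFAULT_MAX_LEN) -> TokenSequence:
    """Encode to a fixed-length id array, zero-padded to ``max_len``.

    Characters outside the training alphabet map to UNK; the mask
    character maps to MASK.  A tokenization longer than ``max_len`` raises
    :class:`SequenceOverflowError` — there is no silent truncation.
    """
    if not smiles:
        raise ValueError("cannot encode an empty string")
    pieces = tokenize(vocab, smiles)
    if len(pieces) > max_len:
        raise SequenceOverflowError(
            f"sequence of {len(pieces)} tokens exceeds max_len={max_len}"
        )
    ids = np.full(max_len, vocab.pad_id, dtype=np.int64)
    for i, tok in enumerate(pieces):
        ids[i] = vocab.token_to_id.get(tok, vocab.unk_id)
    return TokenSequence(ids=ids, true_length=len(pieces))


def decode(vocab: BpeVocabulary, seq: TokenSequence) -> str:
    """Inverse of :func:`encode` for strings over the training alphabet."""
    id_to_token = vocab.id_to_token
    out = []
    for i in seq.ids[: seq.true_length]:
        tok = id_to_token[int(i)]
        if tok == MASK_TOKEN:
            out.append(MASK_CHAR)
        elif tok == UNK_TOKEN:
            out.append("�")
        else:
            out.append(tok)
    return "".join(out)


# spec-facing aliases
save_vocab = BpeVocabulary.save
load_vocab = BpeVocabulary.load
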