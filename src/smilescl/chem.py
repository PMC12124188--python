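"""SMILES handling: canonicalization, enumeration, masking, synthetic corpora.

A molecule admits many valid SMILES strings depending on which atom the
string is rooted at and in which order the graph is traversed.  The
contrastive pre-training in this package exploits exactly that degeneracy:
two different strings for the same molecule form a positive pair.  This
module provides

* :func:`canonicalize` — the unique RDKit canonical form of a SMILES;
* :func:`enumerate_randomized` — a seeded, uniformly atom-shuffled
  rewriting of a SMILES (the "randomized SMILES" augmentation);
* :func:`mask_augment` — character-level masking of up to a budgeted
  fraction of the string (the masking-based augmentation ablation);
* :func:`generate_synthetic_corpus` — a fragment-grammar generator of
  chemically valid, distinct SMILES used as a desk-scale pre-training
  corpus, with controllable ring and heteroatom content;
* plain-text ``.smi`` corpus readers/writers.

All randomness is driven by explicit integer seeds through
``numpy.random.default_rng``; equal inputs and seeds give equal outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem.Scaffolds import MurckoScaffold

RDLogger.DisableLog("rdApp.*")  # parse failures are reported via exceptions

logger = logging.getLogger(__name__)

#: Character used for masked positions. Deliberately outside the SMILES
#: alphabet so masked strings can never be mistaken for chemistry; the
#: tokenizer maps it to its MASK special token.
MASK_CHAR = "?"

CHEMISTRY_BACKEND = f"rdkit-{Chem.rdBase.rdkitVersion}"


class SmilesParseError(ValueError):
    """Raised when a string cannot be parsed as SMILES."""

    def __init__(self, smiles: str, context: str = ""):
        self.smiles = smiles
        msg = f"unparseable SMILES: {smiles!r}"
        if context:
            msg += f" ({context})"
        super().__init__(msg)


@dataclass
class SmilesRecord:
    """One molecule-as-string with provenance.

    ``provenance`` is one of ``original``, ``randomized``, ``masked`` or
    ``synthetic``.  Masked records are exempt from chemical validity: the
    mask character breaks SMILES syntax by design, and such strings flow
    only into the tokenizer, never back into RDKit.
    """

    smiles: str
    provenance: str = "original"
    canonical: str | None = None
    id: str | None = None

    def with_canonical(self) -> "SmilesRecord":
        if self.provenance == "masked":
            return self
        if self.canonical is None:
            self.canonical = canonicalize(self.smiles)
        return self


@dataclass
class CorpusSpec:
    """Parameters of the synthetic-corpus generator.

    ``ring_fraction`` is the probability that a molecule contains a ring;
    ``heteroatom_fraction`` the per-site probability that a chain position
    or substituent introduces a non-carbon atom (N, O, S or a halogen).
    Defaults emulate a small-molecule screening library: most drug-like
    molecules carry at least one ring and several heteroatoms.
    """

    n_molecules: int
    max_smiles_length: int = 60
    ring_fraction: float = 0.4
    heteroatom_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.n_molecules <= 0:
            raise ValueError("n_molecules must be positive")
        if self.max_smiles_length <= 0:
            raise ValueError("max_smiles_length must be positive")
        for name in ("ring_fraction", "heteroatom_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


def _mol_from_smiles(smiles: str, context: str = "") -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles, context)
    return mol


def canonicalize(smiles: str) -> str:
    """Return the backend's canonical SMILES for ``smiles``.

    Idempotent, and identical for any two strings denoting the same
    molecular graph (that is what "canonical" means for the backend).
    Raises :class:`SmilesParseError` on invalid input.
    """
    return Chem.MolToSmiles(_mol_from_smiles(smiles), canonical=True)


def enumerate_randomized(smiles: str, seed: int) -> str:
    """Write ``smiles`` from a uniformly shuffled atom numbering.

    The molecule is parsed, its atom indices are permuted with a seeded
    uniform permutation, and a (generally non-canonical) SMILES is emitted
    rooted at the new first atom.  The output always denotes the same
    molecular graph: ``canonicalize(out) == canonicalize(smiles)``.
    Single-atom molecules admit a single ordering and are returned as-is.
    """
    mol = _mol_from_smiles(smiles, "enumerate_randomized")
    n = mol.GetNumAtoms()
    if n <= 1:
        return smiles
    rng = np.random.default_rng(seed)
    order = [int(i) for i in rng.permutation(n)]
    shuffled = Chem.RenumberAtoms(mol, order)
    return Chem.MolToSmiles(shuffled, canonical=False)


def mask_augment(smiles: str, max_fraction: float = 0.25, seed: int = 0) -> str:
    """Mask a random number of character positions, up to a budget.

    The number of masked positions m is drawn uniformly from
    {0, ..., floor(max_fraction * L)} with L the string length; m distinct
    positions are then replaced by :data:`MASK_CHAR`.  Output length always
    equals input length.  Masked output need not be valid SMILES.
    """
    if not 0.0 <= max_fraction <= 1.0:
        raise ValueError(f"max_fraction must lie in [0, 1], got {max_fraction}")
    L = len(smiles)
    if L == 0:
        return smiles
    rng = np.random.default_rng(seed)
    budget = int(np.floor(max_fraction * L))
    m = int(rng.integers(0, budget + 1))
    if m == 0:
        return smiles
    positions = rng.choice(L, size=m, replace=False)
    chars = list(smiles)
    for p in positions:
        chars[p] = MASK_CHAR
    return "".join(chars)


# --------------------------------------------------------------------------
# Synthetic corpus generation
# --------------------------------------------------------------------------

_PLAIN_RINGS = ["C1CCCCC1", "C1CCCC1", "c1ccccc1"]
_HETERO_RINGS = ["c1ccncc1", "c1ccoc1", "c1ccsc1", "C1CCOC1", "C1CCNC1",
                 "C1CCSC1", "c1ccc2ccccc2c1"]
_CHAIN_HETERO = ["O", "N", "S"]
_BRANCHES_PLAIN = ["(C)", "(CC)", "(C(C)C)"]
_BRANCHES_HETERO = ["(F)", "(Cl)", "(Br)", "(O)", "(N)", "(=O)", "(C#N)",
                    "(OC)", "(NC)"]


def _draw_smiles(rng: np.random.Generator, spec: CorpusSpec) -> str:
    """One grammar draw: an alkyl backbone with optional branches, hetero
    substitutions and at most two ring fragments, joined left to right.

    The grammar is valence-safe by construction (branches attach only to
    carbons, halogens are terminal, rings are self-contained fragments),
    so draws parse with overwhelming probability; the caller still
    validates each string with the chemistry backend.
    """
    hetero = spec.heteroatom_fraction
    use_ring = rng.random() < spec.ring_fraction
    n_units = int(rng.integers(3, 11))
    parts: list[str] = []
    prev_carbon = False
    for _ in range(n_units):
        if hetero > 0 and rng.random() < hetero:
            parts.append(str(rng.choice(_CHAIN_HETERO)))
            prev_carbon = False
        else:
            parts.append("C")
            prev_carbon = True
        if prev_carbon and rng.random() < 0.2:
            pool = _BRANCHES_PLAIN + (_BRANCHES_HETERO if hetero > 0
                                      and rng.random() < hetero * 2 else [])
            parts.append(str(rng.choice(pool)))
    if use_ring:
        pool = list(_PLAIN_RINGS)
        if hetero > 0 and rng.random() < hetero:
            pool = _HETERO_RINGS
        ring = str(rng.choice(pool))
        pos = int(rng.integers(0, len(parts) + 1))
        # never insert a ring between an atom and its branch
        while 0 < pos < len(parts) and parts[pos].startswith("("):
            pos += 1
        parts.insert(pos, ring)
    return "".join(parts)


def generate_synthetic_corpus(spec: CorpusSpec) -> list[SmilesRecord]:
    """Generate ``spec.n_molecules`` distinct, parseable synthetic SMILES.

    Distinctness is enforced on canonical forms.  Deterministic for equal
    specs (including the seed).  Raises if the grammar cannot supply enough
    distinct molecules within the length bound.
    """
    rng = np.random.default_rng(spec.seed)
    records: list[SmilesRecord] = []
    seen: set[str] = set()
    attempts = 0
    max_attempts = 200 * spec.n_molecules + 1000
    while len(records) < spec.n_molecules:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"synthetic grammar exhausted after {attempts} draws: "
                f"cannot produce {spec.n_molecules} distinct molecules with "
                f"max_smiles_length={spec.max_smiles_length}"
            )
        s = _draw_smiles(rng, spec)
        if len(s) > spec.max_smiles_length:
            continue
        mol = Chem.MolFromSmiles(s)
        if mol is None:
            continue
        canonical = Chem.MolToSmiles(mol, canonical=True)
        if canonical in seen:
            continue
        seen.add(canonical)
        records.append(SmilesRecord(smiles=s, provenance="synthetic",
                                    canonical=canonical,
                                    id=f"syn{len(records):06d}"))
    return records


def murcko_scaffold(smiles: str) -> str:
    """Bemis–Murcko scaffold SMILES (empty string for acyclic molecules)."""
    return MurckoScaffold.MurckoScaffoldSmiles(smiles=smiles)


def contains_element(smiles: str, symbol: str) -> bool:
    """True if the molecule contains an atom with the given element symbol."""
    mol = _mol_from_smiles(smiles, "contains_element")
    return any(a.GetSymbol() == symbol for a in mol.GetAtoms())


# --------------------------------------------------------------------------
# Corpus file I/O (.smi: one record per line, "SMILES[<ws>NAME]", # comments)
# --------------------------------------------------------------------------

def write_smiles_file(records: Iterable[SmilesRecord], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for rec in records:
            if rec.id:
                fh.write(f"{rec.smiles}\t{rec.id}\n")
            else:
                fh.write(f"{rec.smiles}\n")


def read_smiles_file(path: str | Path, on_invalid: str = "abort",
                     validate: bool = True) -> list[SmilesRecord]:
    """Read a ``.smi`` file into records.

    Blank lines and ``#`` comment lines are skipped (their count is logged).
    ``on_invalid`` controls what happens to lines whose SMILES does not
    parse: ``"abort"`` (default) raises naming the line number, ``"skip"``
    drops the line with a logged warning.
    """
    if on_invalid not in ("abort", "skip"):
        raise ValueError("on_invalid must be 'abort' or 'skip'")
    path = Path(path)
    records: list[SmilesRecord] = []
    n_skipped_blank = 0
    n_skipped_invalid = 0
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                n_skipped_blank += 1
                continue
            fields = stripped.split()
            smiles = fields[0]
            name = fields[1] if len(fields) > 1 else None
            if validate and Chem.MolFromSmiles(smiles) is None:
                if on_invalid == "abort":
                    raise SmilesParseError(smiles, f"{path} line {lineno}")
                n_skipped_invalid += 1
                logger.warning("skipping invalid SMILES at %s line %d: %r",
                               path, lineno, smiles)
                continue
            records.append(SmilesRecord(smiles=smiles, id=name))
    if n_skipped_blank:
        logger.info("skipped %d blank/comment line(s) in %s",
                    n_skipped_blank, path)
    if n_skipped_invalid:
        logger.info("skipped %d invalid line(s) in %s", n_skipped_invalid, path)
    return records


# --------------------------------------------------------------------------
# Plantable label signals for desk-scale fine-tuning studies
# --------------------------------------------------------------------------

def plant_labels(records: Sequence[SmilesRecord], task: str = "nitrogen",
                 ) -> np.ndarray:
    """Construct a label vector with a known, learnable signal.

    ``"nitrogen"``: binary, 1 if the molecule contains at least one nitrogen
    atom.  ``"length"``: real-valued, a linear function of heavy-atom count
    (a regression target whose information is plainly present in the
    string).  Used to test that fine-tuning can recover a signal the
    representation must carry.
    """
    if task == "nitrogen":
        return np.array([float(contains_element(r.smiles, "N"))
                         for r in records])
    if task == "length":
        counts = np.array([_mol_from_smiles(r.smiles).GetNumAtoms()
                           for r in records], dtype=float)
        return 0.5 * counts - 2.0
    raise ValueError(f"unknown plantable task {task!r}")
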