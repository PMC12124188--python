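# Methods

## Overview

`smilescl` implements contrastive self-supervised learning of SMILES
representations. The premise: a molecule admits many valid SMILES strings
depending on atom numbering, so two different strings for the same molecule
are free "views" of one object. A transformer encoder is trained so that
embeddings of such views agree (positive pairs) while embeddings of
different molecules in the same mini-batch disagree (negatives). The
pre-trained encoder is then fine-tuned with a single linear head for
molecular property prediction, and its invariance to SMILES rewriting is
quantified with cosine similarity.

## Data processing

**Randomized SMILES.** A SMILES is parsed with RDKit, atom indices are
permuted with a seeded uniform permutation, and a non-canonical SMILES is
written from the shuffled numbering. The output always denotes the same
molecular graph (`canonicalize(out) == canonicalize(in)` is asserted
property-style in the tests). Stereo descriptors are preserved exactly as
RDKit emits them; no restricted or canonical-rooted variants are used.
Single-atom molecules admit one string and are returned unchanged.

**Masked SMILES (ablation augmentation).** An alternative augmentation
replaces a random number of character positions — drawn uniformly from
{0, ..., floor(f·L)} with budget f = 0.25 by default — with a reserved mask
character (`?`, deliberately outside the SMILES alphabet). Masked strings
generally break SMILES syntax; they flow only into the tokenizer (the mask
character maps to the MASK token), never into RDKit. The mask unit is the
character; token-level masking was considered and rejected to keep the
budget interpretable on the raw string.

**Tokenization.** A byte-pair-encoding vocabulary of exactly 300 tokens
(PAD, UNK and MASK counted inside the budget; PAD is id 0) is trained on
the corpus character alphabet by iteratively merging the most frequent
adjacent pair. Ties break to the lexicographically smallest pair so
retraining is bit-reproducible. Encoding applies merges in training order
and zero-pads to a fixed maximum length (512 at full scale); a sequence
that does not fit raises rather than being truncated silently, since the
padding convention presumes inputs fit. Encode→decode is exact over the
training alphabet.

**Synthetic corpus generator.** Desk-scale experiments use a fragment
grammar instead of an external compound library: alkyl backbones of 3–10
units with optional branches, O/N/S chain substitutions, terminal halogen
or carbonyl/nitrile branches, and 5-/6-membered aliphatic, aromatic and
fused-aromatic rings. `ring_fraction` (default 0.4) is the probability a
molecule carries a ring; `heteroatom_fraction` (default 0.3) the per-site
probability of a heteroatom — defaults chosen to resemble a small-molecule
screening library in which most compounds carry rings and several
heteroatoms. Every draw is validated and canonicalized with RDKit and
distinctness is enforced on canonical forms. The grammar emulates the
*string statistics* real corpora stress (branching, ring closures,
aromaticity, heteroatoms) but not their chemical diversity: molecules are
small (≤ 60 characters), functional-group variety is narrow, and there is
no stereochemistry or charge. Tests passing on this corpus therefore
demonstrate the machinery's correctness and trainability, not
benchmark-level chemical generalization.

## Model

Token ids are embedded (scaled by √d_model), fixed sinusoidal positional
encodings are added, and the sequence passes through pre-norm transformer
blocks (self-attention plus a GELU feed-forward of width 4·d_model,
dropout 0.1) and a final layer norm. Full-scale defaults follow the
reference configuration: d_model 768, 2 layers, 8 heads, context 512,
vocabulary 300. Positional encodings are sinusoidal rather than learned
because they are parameter-free and reproducible; the reference
architecture does not specify a variant.

Two output vectors are exposed per sequence:

* **pooled** — global average pooling of per-token outputs over non-pad
  positions only (zero-padding must not dilute the molecular content);
* **projected** — the pooled vector passed through a linear layer.

The contrastive loss is applied to the projected vectors; downstream
fine-tuning and the robustness study consume the pooled vector by default
(the usual SimCLR-style convention of discarding the projection head), with
a flag to switch. Attention never attends to PAD keys, so PAD content
cannot leak into non-pad outputs; because trailing all-PAD columns
contribute exact zeros, each forward pass is trimmed to the longest true
sequence in the batch with no change to any output.

The training stack (reverse-mode autodiff, transformer layers, AdamW) is
implemented in the package on NumPy in float64; gradients are verified
against central finite differences in the test suite.

## Contrastive pre-training

Each batch holds N distinct molecules (distinctness checked on canonical
forms — a duplicate would be treated as a false negative). The anchor view
is the original string; the positive view is its randomized (default) or
masked rewriting. All 2N projected embeddings are stacked and the
symmetric NT-Xent loss is applied with temperature τ:

    L = (1/2N) Σ_i −log [ exp(sim(z_i, z_{p(i)})/τ)
                          / Σ_{k≠i} exp(sim(z_i, z_k)/τ) ]

where sim is cosine similarity, p(i) is the other view of molecule i, and
the denominator runs over all other 2N−1 views. With random embeddings the
softmax is near-uniform and the loss sits near ln(2N−1) — a useful analytic
anchor checked at the start of every training run. The symmetric 2N-anchor
form (every view is an anchor once) is used throughout; it is the standard
in-batch formulation of this loss.

Full-scale defaults: batch 128, learning rate 1e-4, τ = 0.2, AdamW
(default decoupled weight decay 0.01, no learning-rate schedule — none is
specified for the reference setup), 16 epochs. Molecules are sampled
without replacement per epoch and the last incomplete batch is dropped so N
is constant. One master seed fans out (via `numpy.random.SeedSequence`)
to independent streams for initialization, shuffling, dropout, and
per-(epoch, batch, slot) augmentation, so runs are exactly reproducible.

## Desk-scale study conditions

The test suite and `scripts/acceptance.py` run the pipeline end to end at
a configuration sized for a single CPU:

* corpus: 2000 synthetic molecules (generator defaults above);
* encoder: d_model 64, 2 layers, 8 heads, context 128, vocabulary 300;
* pre-training: batch 32, τ = 0.2, 5 epochs, learning rate 1e-3 (a
  standard choice for a model this small trained for few steps; the
  full-scale default remains 1e-4);
* fine-tuning: 1200 molecules, planted nitrogen-presence label,
  60/20/20 random split, 20 epochs, patience 10;
* robustness: 200 held-out molecules (disjoint by canonical form from the
  pre-training corpus), 5 randomizations per molecule, pooled vectors.

## Fine-tuning

A single linear layer sits on the chosen representation; the encoder is
fine-tuned jointly by default (freezing is a flag). Classification uses
per-task binary cross-entropy averaged over non-missing entries only —
multi-task panels routinely have missing labels, which are masked inside
the loss and never imputed. Regression standardizes targets per task
(de-standardized at prediction) for optimizer stability. Early stopping
monitors the validation metric with patience 10 and restores the best
weights. Fine-tuning always operates on a copy of the encoder, so a
checkpoint can serve several runs.

Splits are random 80/10/10 by default; a Bemis–Murcko scaffold split is
available (whole scaffold groups assigned largest-first to train, then
validation, then test) so structurally similar molecules never straddle
splits. Multi-task metrics (AUC-ROC for classification, RMSE/MAE for
regression) average per-task values, excluding single-class tasks from
the AUC mean with a logged warning.

## Robustness study

For each molecule the canonical SMILES and n randomized rewritings
(default 5) are embedded; the per-molecule score is the mean cosine
similarity between the canonical embedding and each variant embedding, and
the report aggregates mean and standard deviation across molecules.
Averaging per molecule first keeps every molecule equally weighted
regardless of n. Two reports over the same molecules are compared by the
paired mean difference plus a sign test. At the desk-scale conditions the
contrastively pre-trained encoder scores strictly higher than a randomly
initialized one; note that random transformers are anisotropic (they map
everything to a narrow cone, inflating the baseline similarity), so the
contrast is informative specifically because pre-training must beat that
inflated baseline.

## Numerical choices and degenerate inputs

* Cosine similarity raises on zero vectors (undefined) and clips to
  [−1, 1] against rounding.
* NT-Xent requires N ≥ 2; with N = 1 the denominator would contain only
  the positive. Self-similarity is excluded with a −1e9 additive mask and
  the log-sum-exp is max-shifted.
* Softmax, GELU (tanh approximation), and layer normalization use fused
  closed-form backward passes, validated against finite differences.
* Non-finite training loss aborts with diagnostics rather than continuing.
* Checkpoints store weights (`.npz`) beside a JSON sidecar carrying the
  encoder configuration, the full vocabulary and its SHA-256 fingerprint;
  loading verifies internal consistency and, when a vocabulary is
  supplied, its fingerprint.

## Known limitations

* The synthetic grammar cannot stand in for real compound libraries; all
  quantitative results in this repository characterize the method at desk
  scale, not benchmark performance.
* Full-scale defaults (d_model 768, batch 128, 1M-molecule corpora) are
  supported by the configuration surface but are far slower on the NumPy
  stack than on a GPU deep-learning framework; the package targets
  correctness, reproducibility and desk-scale study, not throughput.
* The reference setup leaves the exact data split protocol, fine-tuning
  schedule and small-model width unspecified; these are exposed as
  configuration with the defaults declared above.
* Masked-string augmentation can delete chemically load-bearing characters;
  it is provided as the ablation alternative, not the default.
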