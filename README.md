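# smilescl

Contrastive self-supervised learning of SMILES representations for
molecular property prediction.

A molecule has many valid SMILES strings — shuffle the atom numbering and
RDKit will happily write a different string for the same graph. `smilescl`
treats two such strings as two views of one object and pre-trains a small
transformer encoder with the NT-Xent contrastive loss so that views of the
same molecule embed close together while different molecules in the batch
are pushed apart:

    ℓ_i = −log  exp(sim(z_i, ẑ_i)/τ) / Σ_{k≠i} exp(sim(z_i, z_k)/τ)

with `sim` the cosine similarity, τ the temperature (default 0.2), and the
sum running over the other 2N−1 embeddings of an N-molecule batch. The
pre-trained encoder is fine-tuned with a single linear head for
classification (AUC-ROC) or regression (RMSE/MAE), and its invariance to
SMILES rewriting is measured as the cosine similarity between embeddings
of canonical and randomized strings.

The package is aimed at practitioners who want a transparent, fully
inspectable reference implementation of this training recipe: chemistry
through RDKit, a hand-written BPE tokenizer with pinned tie-breaking, and
a NumPy transformer/autodiff stack whose gradients are tested against
finite differences. Everything is seeded and reproducible on one CPU.

## Worked example

```python
import smilescl as sc

# 1. synthetic corpus (or read your own .smi file)
corpus = sc.generate_synthetic_corpus(sc.CorpusSpec(n_molecules=2000, seed=42))

# 2. contrastive pre-training, sklearn-style
enc = sc.ContrastiveSmilesEncoder(
    d_model=64, n_layers=2, n_heads=8, max_len=128, vocab_size=300,
    batch_size=32, temperature=0.2, learning_rate=1e-3, epochs=5, seed=0,
).fit([r.smiles for r in corpus])
print([round(l, 3) for l in enc.loss_history_])

# 3. embeddings for any SMILES
Z = enc.transform(["CC(C)Cc1ccc(cc1)C(C)C(=O)O", "c1ccccc1"])
print(Z.shape)
```

prints (the exact numbers are reproduced by the seeds above):

```
[3.787, 3.085, 2.592, 2.251, 2.035]
(2, 64)
```

The first epoch starts near the random-embedding limit ln(2·32−1) ≈ 4.14
and falls as positive pairs align. Fine-tuning and the robustness report:

```python
from smilescl.chem import plant_labels

data = sc.generate_synthetic_corpus(sc.CorpusSpec(n_molecules=1200, seed=777))
clf = sc.SmilesClassifier(encoder=enc, epochs=20, seed=1)
clf.fit([r.smiles for r in data], plant_labels(data, "nitrogen"))

report = sc.robustness_study(enc.model_, data[:100], n_randomizations=5, seed=7)
print(round(report.mean, 3), round(report.std, 3))
```

which prints `0.795 0.09`. The classifier recovers a planted "contains
nitrogen" label almost perfectly (held-out AUC > 0.99 in the bundled
tests), and `report.mean` is the average cosine similarity between each
molecule's canonical-SMILES embedding and five randomized rewritings —
0.795 after this tiny pre-training run versus 0.565 for the same encoder
left at random initialization.

A command-line interface mirrors the library:

```bash
smilescl generate-corpus --n 2000 --seed 42 --out corpus.smi
smilescl train-tokenizer --corpus corpus.smi --vocab-size 300 --out vocab.json
smilescl pretrain --corpus corpus.smi --vocab vocab.json --seed 0 --out ckpt/
smilescl embed --checkpoint ckpt/checkpoint --in corpus.smi --out embeddings.csv
smilescl robustness --checkpoint ckpt/checkpoint --in corpus.smi --out report.json
```

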