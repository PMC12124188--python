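"""Splits, metrics, and masked-loss fine-tuning behaviour."""

import itertools
import logging

import numpy as np
import pandas as pd
import pytest

import smilescl as sc
from smilescl._autodiff import Tensor
from smilescl.chem import murcko_scaffold, plant_labels
from smilescl.downstream import _masked_bce_loss, _masked_mse_loss


def brute_force_auc(scores, labels):
    """Pair-counting definition: P(random positive outscores a random
    negative), ties counted one half."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p, n in itertools.product(pos, neg))
    return wins / (len(pos) * len(neg))


@pytest.fixture(scope="module")
def dataset(small_corpus):
    records = small_corpus[:100]
    y = plant_labels(records, "nitrogen")
    return sc.LabeledDataset(records, y, ["nitrogen"])


class TestLabeledDataset:
    def test_missing_cells_become_nan_mask(self, tmp_path):
        df = pd.DataFrame({"smiles": ["CCO", "CCN", "CCC"],
                           "t1": [1.0, None, 0.0],
                           "t2": [None, 1.0, 1.0]})
        path = tmp_path / "d.csv"
        df.to_csv(path, index=False)
        ds = sc.LabeledDataset.from_csv(path)
        assert ds.task_names == ["t1", "t2"]
        assert ds.missing_mask.tolist() == [[False, True], [True, False],
                                            [False, False]]

    def test_shape_mismatches_rejected(self):
        recs = [sc.SmilesRecord("CC"), sc.SmilesRecord("CCC")]
        with pytest.raises(ValueError):
            sc.LabeledDataset(recs, np.ones((3, 1)), ["t"])
        with pytest.raises(ValueError):
            sc.LabeledDataset(recs, np.ones((2, 2)), ["t"])


class TestSplits:
    def test_random_split_sizes_and_cover(self, dataset):
        train, valid, test = sc.split_dataset(dataset, "random",
                                              (0.8, 0.1, 0.1), seed=0)
        assert (len(train), len(valid), len(test)) == (80, 10, 10)
        all_smiles = sorted(r.smiles for part in (train, valid, test)
                            for r in part.records)
        assert all_smiles == sorted(r.smiles for r in dataset.records)

    def test_random_split_deterministic(self, dataset):
        a = sc.split_dataset(dataset, "random", seed=5)
        b = sc.split_dataset(dataset, "random", seed=5)
        assert [r.smiles for r in a[0].records] == \
               [r.smiles for r in b[0].records]

    def test_scaffold_split_never_shares_scaffolds(self, dataset):
        parts = sc.split_dataset(dataset, "scaffold", (0.7, 0.15, 0.15),
                                 seed=0)
        keys = [{murcko_scaffold(r.smiles) for r in p.records}
                for p in parts]
        assert not keys[0] & keys[1]
        assert not keys[0] & keys[2]
        assert not keys[1] & keys[2]

    def test_empty_split_rejected(self, dataset):
        tiny = dataset.subset(range(5))
        with pytest.raises(ValueError, match="zero records"):
            sc.split_dataset(tiny, "random", (0.9, 0.05, 0.05), seed=0)

    def test_bad_fractions_rejected(self, dataset):
        with pytest.raises(ValueError, match="fractions"):
            sc.split_dataset(dataset, "random", (0.8, 0.1, 0.2), seed=0)


class TestMetrics:
    def test_perfect_separation_gives_one(self):
        assert sc.auc_roc([0.9, 0.8, 0.1], [1, 1, 0]) == 1.0

    def test_known_mixed_ranking(self):
        assert sc.auc_roc([0.9, 0.8, 0.3, 0.2],
                          [1, 0, 1, 0]) == pytest.approx(0.75)

    def test_matches_brute_force_pair_counting_with_ties(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            scores = rng.integers(0, 5, size=30).astype(float)  # forces ties
            labels = rng.integers(0, 2, size=30).astype(float)
            if len(np.unique(labels)) < 2:
                continue
            assert sc.auc_roc(scores, labels) == pytest.approx(
                brute_force_auc(scores, labels))

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(8)
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, size=40).astype(float)
        a = sc.auc_roc(scores, labels)
        assert sc.auc_roc(np.exp(3 * scores) + 7, labels) == pytest.approx(a)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            sc.auc_roc([0.1, 0.9], [1, 1])

    def test_rmse_mae_basics(self):
        x = np.array([1.0, 2.0, 3.0])
        assert sc.rmse(x, x) == 0.0
        assert sc.mae(x, x) == 0.0
        assert sc.rmse([0.0, 0.0], [3.0, 4.0]) == pytest.approx(np.sqrt(12.5))
        assert sc.mae([0.0, 0.0], [3.0, 4.0]) == pytest.approx(3.5)

    def test_multitask_mean_matches_per_task_recomputation(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=(50, 3))
        labels = rng.integers(0, 2, size=(50, 3)).astype(float)
        labels[rng.random(size=labels.shape) < 0.2] = np.nan
        expected = []
        for t in range(3):
            obs = ~np.isnan(labels[:, t])
            expected.append(brute_force_auc(scores[obs, t], labels[obs, t]))
        got = sc.multitask_metric(scores, labels, "auc_roc")
        assert got == pytest.approx(np.mean(expected))

    def test_single_class_task_excluded_with_warning(self, caplog):
        scores = np.array([[0.9, 0.2], [0.1, 0.4], [0.8, 0.9]])
        labels = np.array([[1.0, 1.0], [0.0, 1.0], [1.0, 1.0]])
        with caplog.at_level(logging.WARNING, logger="smilescl.downstream"):
            got = sc.multitask_metric(scores, labels, "auc_roc")
        assert "single observed class" in caplog.text
        assert got == pytest.approx(sc.auc_roc(scores[:, 0], labels[:, 0]))

    def test_no_evaluable_task_rejected(self):
        with pytest.raises(ValueError, match="no evaluable"):
            sc.multitask_metric(np.ones((3, 1)), np.ones((3, 1)), "auc_roc")


class TestMaskedLosses:
    def test_all_missing_record_leaves_bce_unchanged(self):
        rng = np.random.default_rng(0)
        logits = rng.normal(size=(5, 2))
        labels = rng.integers(0, 2, size=(5, 2)).astype(float)
        base = _masked_bce_loss(Tensor(logits), labels).item()
        logits_ext = np.vstack([logits, rng.normal(size=(1, 2))])
        labels_ext = np.vstack([labels, np.full((1, 2), np.nan)])
        extended = _masked_bce_loss(Tensor(logits_ext), labels_ext).item()
        assert extended == pytest.approx(base, abs=1e-12)

    def test_bce_matches_manual_formula(self):
        logits = np.array([[0.5, -1.0], [2.0, 0.0]])
        labels = np.array([[1.0, 0.0], [np.nan, 1.0]])
        obs = ~np.isnan(labels)
        manual = np.mean([
            np.log1p(np.exp(-l)) if y == 1 else np.log1p(np.exp(l))
            for l, y in zip(logits[obs], labels[obs])])
        got = _masked_bce_loss(Tensor(logits), labels).item()
        assert got == pytest.approx(manual)

    def test_mse_ignores_missing_entries(self):
        pred = np.array([[1.0], [2.0], [3.0]])
        target = np.array([[1.5], [np.nan], [2.0]])
        got = _masked_mse_loss(Tensor(pred), target).item()
        assert got == pytest.approx((0.25 + 1.0) / 2)


class TestFinetune:
    def test_all_missing_task_rejected(self, small_corpus, small_vocab):
        enc = sc.build_encoder(
            sc.EncoderConfig(d_model=16, n_layers=1, n_heads=2, max_len=64,
                             vocab_size=small_vocab.size),
            vocab=small_vocab)
        records = small_corpus[:40]
        y = np.column_stack([plant_labels(records, "nitrogen"),
                             np.full(40, np.nan)])
        ds = sc.LabeledDataset(records, y, ["nitrogen", "empty"])
        splits = sc.split_dataset(ds, "random", (0.6, 0.2, 0.2), seed=0)
        spec = sc.TaskSpec("classification", 2, "auc_roc")
        with pytest.raises(ValueError, match="empty"):
            sc.finetune(enc, splits, spec)

    def test_regression_learns_linear_length_signal(self, small_corpus,
                                                    small_vocab):
        enc = sc.build_encoder(
            sc.EncoderConfig(d_model=16, n_layers=1, n_heads=2, max_len=64,
                             vocab_size=small_vocab.size, dropout=0.0,
                             seed=2),
            vocab=small_vocab)
        records = small_corpus
        y = plant_labels(records, "length")
        ds = sc.LabeledDataset(records, y, ["length"])
        splits = sc.split_dataset(ds, "random", (0.7, 0.15, 0.15), seed=3)
        spec = sc.TaskSpec("regression", 1, "rmse")
        cfg = sc.FinetuneConfig(learning_rate=1e-3, epochs=15, batch_size=32,
                                seed=3)
        tuned = sc.finetune(enc, splits, spec, cfg)
        test = splits[2]
        pred = tuned.predict(test.records)[:, 0]
        achieved = sc.rmse(pred, test.labels[:, 0])
        assert achieved < np.std(test.labels[:, 0])

    def test_finetune_does_not_mutate_the_checkpoint(self, small_corpus,
                                                     small_vocab):
        enc = sc.build_encoder(
            sc.EncoderConfig(d_model=16, n_layers=1, n_heads=2, max_len=64,
                             vocab_size=small_vocab.size, seed=4),
            vocab=small_vocab)
        before = {k: v.copy() for k, v in enc.state_dict().items()}
        records = small_corpus[:60]
        ds = sc.LabeledDataset(records, plant_labels(records, "nitrogen"),
                               ["nitrogen"])
        splits = sc.split_dataset(ds, "random", (0.6, 0.2, 0.2), seed=0)
        sc.finetune(enc, splits, sc.TaskSpec("classification", 1, "auc_roc"),
                    sc.FinetuneConfig(epochs=2, seed=0))
        after = enc.state_dict()
        assert all(np.array_equal(before[k], after[k]) for k in before)

    def test_incompatible_task_metric_rejected(self):
        with pytest.raises(ValueError, match="incompatible"):
            sc.TaskSpec("classification", 1, "rmse")
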