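"""Contrastive machinery: cosine similarity, NT-Xent, batches, training."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import smilescl as sc
from smilescl._autodiff import Tensor, concat
from smilescl.contrastive import _nt_xent_stacked


def brute_force_nt_xent(Z, Z_aug, tau):
    """Literal double-loop transcription of the symmetric in-batch loss."""
    A = np.vstack([Z, Z_aug])
    n2 = len(A)
    N = n2 // 2

    def sim(a, b):
        return float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))

    total = 0.0
    for i in range(n2):
        p = i + N if i < N else i - N
        num = math.exp(sim(A[i], A[p]) / tau)
        den = 0.0
        for k in range(n2):
            if k != i:
                den += math.exp(sim(A[i], A[k]) / tau)
        total += -math.log(num / den)
    return total / n2


class TestCosineSimilarity:
    def test_self_similarity_is_one(self):
        v = np.array([1.0, 2.0, -3.0])
        assert sc.cosine_similarity(v, v) == pytest.approx(1.0)

    def test_orthogonal_vectors(self):
        assert sc.cosine_similarity([1, 0], [0, 1]) == pytest.approx(0.0)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError, match="zero vector"):
            sc.cosine_similarity([0.0, 0.0], [1.0, 0.0])

    @settings(deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.floats(0.1, 50.0))
    def test_scale_invariance_and_symmetry(self, seed, scale):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=5), rng.normal(size=5)
        s = sc.cosine_similarity(a, b)
        assert sc.cosine_similarity(scale * a, b) == pytest.approx(s)
        assert sc.cosine_similarity(b, a) == pytest.approx(s)
        assert -1.0 <= s <= 1.0


class TestNtXentLoss:
    @pytest.mark.parametrize("N", [2, 4, 8])
    def test_identical_embeddings_give_log_2n_minus_1(self, N):
        Z = np.ones((N, 6))
        assert sc.nt_xent_loss(Z, Z, 0.2) == pytest.approx(np.log(2 * N - 1))

    def test_two_pairs_give_ln_three(self):
        Z = np.tile([0.3, -1.2, 0.5], (2, 1))
        assert sc.nt_xent_loss(Z, Z, 0.2) == pytest.approx(math.log(3.0))

    @pytest.mark.parametrize("N", [2, 4, 8])
    @pytest.mark.parametrize("dim", [4, 16])
    def test_matches_brute_force_double_loop(self, N, dim):
        rng = np.random.default_rng(N * 100 + dim)
        for _ in range(5):
            Z = rng.normal(size=(N, dim))
            Za = rng.normal(size=(N, dim))
            v = sc.nt_xent_loss(Z, Za, 0.2)
            assert v == pytest.approx(brute_force_nt_xent(Z, Za, 0.2),
                                      abs=1e-6)

    def test_large_temperature_flattens_to_log_2n_minus_1(self):
        rng = np.random.default_rng(0)
        Z, Za = rng.normal(size=(4, 8)), rng.normal(size=(4, 8))
        assert sc.nt_xent_loss(Z, Za, 1e6) == pytest.approx(np.log(7),
                                                            abs=1e-4)

    def test_single_pair_rejected(self):
        Z = np.ones((1, 4))
        with pytest.raises(ValueError, match="N >= 2"):
            sc.nt_xent_loss(Z, Z, 0.2)

    def test_loss_positive_and_decreases_with_positive_alignment(self):
        rng = np.random.default_rng(3)
        Z = rng.normal(size=(4, 8))
        noise = rng.normal(size=(4, 8))
        losses = [sc.nt_xent_loss(Z, Z + a * noise, 0.2)
                  for a in (1.0, 0.5, 0.1, 0.0)]
        assert all(l > 0 for l in losses)
        assert losses == sorted(losses, reverse=True)

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(1)
        Z = rng.normal(size=(3, 5))
        Za = rng.normal(size=(3, 5))
        t = Tensor(Z, requires_grad=True)
        loss = _nt_xent_stacked(concat([t, Tensor(Za)]), 3, 0.2)
        loss.backward()
        eps, num = 1e-6, np.zeros_like(Z)
        for i in range(3):
            for j in range(5):
                zp, zm = Z.copy(), Z.copy()
                zp[i, j] += eps
                zm[i, j] -= eps
                num[i, j] = (brute_force_nt_xent(zp, Za, 0.2)
                             - brute_force_nt_xent(zm, Za, 0.2)) / (2 * eps)
        assert np.allclose(t.grad, num, atol=1e-6)


class TestMakeBatch:
    @pytest.fixture()
    def config(self):
        return sc.PretrainConfig(batch_size=8, seed=3)

    def test_randomized_positives_denote_same_molecule(self, small_corpus,
                                                       small_vocab, config):
        records = small_corpus[:8]
        batch = sc.make_batch(records, small_vocab, config, max_len=64)
        for rec, anchor, pos in zip(records, batch.anchors, batch.positives):
            assert sc.decode(small_vocab, anchor) == rec.smiles
            pos_smiles = sc.decode(small_vocab, pos)
            assert sc.canonicalize(pos_smiles) == rec.canonical

    def test_masked_positives_within_hamming_budget(self, small_corpus,
                                                    small_vocab):
        config = sc.PretrainConfig(batch_size=8, augmentation="masked",
                                   seed=1)
        records = small_corpus[:8]
        batch = sc.make_batch(records, small_vocab, config, max_len=64)
        for rec, pos in zip(records, batch.positives):
            masked = sc.decode(small_vocab, pos)
            assert len(masked) == len(rec.smiles)
            diff = sum(a != b for a, b in zip(masked, rec.smiles))
            assert diff <= int(0.25 * len(rec.smiles))

    def test_duplicate_molecules_rejected(self, small_corpus, small_vocab,
                                          config):
        records = small_corpus[:7] + [small_corpus[0]]
        with pytest.raises(ValueError, match="duplicate"):
            sc.make_batch(records, small_vocab, config, max_len=64)

    def test_deterministic_per_epoch_and_index(self, small_corpus,
                                               small_vocab, config):
        records = small_corpus[:8]
        a = sc.make_batch(records, small_vocab, config, max_len=64,
                          epoch=2, batch_index=5)
        b = sc.make_batch(records, small_vocab, config, max_len=64,
                          epoch=2, batch_index=5)
        c = sc.make_batch(records, small_vocab, config, max_len=64,
                          epoch=3, batch_index=5)
        same = all(np.array_equal(x.ids, y.ids)
                   for x, y in zip(a.positives, b.positives))
        diff = any(not np.array_equal(x.ids, y.ids)
                   for x, y in zip(a.positives, c.positives))
        assert same and diff


class TestPretrainLoop:
    def test_corpus_smaller_than_batch_rejected(self, small_corpus):
        enc = sc.EncoderConfig(d_model=16, n_layers=1, n_heads=2, max_len=64,
                               vocab_size=80)
        pre = sc.PretrainConfig(batch_size=512)
        with pytest.raises(ValueError, match="smaller"):
            sc.pretrain(small_corpus, enc, pre)

    def test_invalid_hyperparameters_rejected(self):
        with pytest.raises(ValueError):
            sc.PretrainConfig(temperature=0.0)
        with pytest.raises(ValueError):
            sc.PretrainConfig(batch_size=1)
        with pytest.raises(ValueError):
            sc.PretrainConfig(augmentation="rotated")

    def test_short_run_is_reproducible_and_logged(self, small_corpus):
        enc = sc.EncoderConfig(d_model=16, n_layers=1, n_heads=2, max_len=64,
                               vocab_size=80, seed=0)
        pre = sc.PretrainConfig(batch_size=16, learning_rate=1e-3, epochs=2,
                                seed=9)
        _, log_a = sc.pretrain(small_corpus[:64], enc, pre)
        _, log_b = sc.pretrain(small_corpus[:64], enc, pre)
        assert len(log_a.losses) == 2
        assert log_a.initial_loss == pytest.approx(log_b.initial_loss,
                                                   abs=1e-5)
        assert np.allclose(log_a.losses, log_b.losses, atol=1e-5)

    def test_log_serialization(self, tmp_path):
        log = sc.TrainingLog(initial_loss=4.0, epochs=[
            {"epoch": 1, "mean_loss": 3.5, "lr": 1e-3, "wall_time": 0.1}])
        log.to_csv(tmp_path / "log.csv")
        log.to_jsonl(tmp_path / "log.jsonl")
        assert "mean_loss" in (tmp_path / "log.csv").read_text()
        assert "initial_eval" in (tmp_path / "log.jsonl").read_text()
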