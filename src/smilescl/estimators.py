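"""scikit-learn-style estimators wrapping the contrastive SMILES pipeline.

``ContrastiveSmilesEncoder`` is a transformer in the sklearn sense: ``fit``
on a list of SMILES strings runs BPE-vocabulary training plus contrastive
pre-training, ``transform`` maps SMILES to fixed-width embedding vectors.
``SmilesClassifier``/``SmilesRegressor`` fine-tune a (pre-trained or fresh)
encoder with a linear head.  All three follow the estimator contract:
constructor stores hyperparameters untouched, fitted state lives in
trailing-underscore attributes, and ``get_params``/``set_params``/``clone``
work, so the estimators compose with sklearn pipelines and model selection.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .chem import SmilesRecord
from .contrastive import PretrainConfig, pretrain
from .downstream import (FinetuneConfig, LabeledDataset, TaskSpec, finetune,
                         split_dataset)
from .encoder import EncoderConfig, SmilesEncoder


def _as_smiles_list(X) -> list[str]:
    if hasattr(X, "tolist"):
        X = X.tolist()
    X = [x[0] if isinstance(x, (list, tuple, np.ndarray)) else x for x in X]
    if not X:
        raise ValueError("X is empty")
    if not all(isinstance(s, str) and s for s in X):
        raise ValueError("X must be a sequence of non-empty SMILES strings")
    return list(X)


class ContrastiveSmilesEncoder(TransformerMixin, BaseEstimator):
    """Self-supervised SMILES embedding via contrastive pre-training.

    Parameters mirror the encoder architecture and the pre-training loop;
    defaults are the full-scale settings (width 768, batch 128, lr 1e-4,
    temperature 0.2, 16 epochs).  Desk-scale use shrinks ``d_model``,
    ``max_len``, ``batch_size`` and ``epochs``.
    """

    def __init__(self, d_model=768, n_layers=2, n_heads=8, max_len=512,
                 vocab_size=300, projection_dim=None, dropout=0.1,
                 batch_size=128, temperature=0.2, learning_rate=1e-4,
                 epochs=16, augmentation="randomized", mask_fraction=0.25,
                 representation="pooled", seed=0):
        self.d_model = d_model
        self.n_layers = n_layers
        self.n_heads = n_heads
        self.max_len = max_len
        self.vocab_size = vocab_size
        self.projection_dim = projection_dim
        self.dropout = dropout
        self.batch_size = batch_size
        self.temperature = temperature
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.augmentation = augmentation
        self.mask_fraction = mask_fraction
        self.representation = representation
        self.seed = seed

    def _configs(self) -> tuple[EncoderConfig, PretrainConfig]:
        enc = EncoderConfig(d_model=self.d_model, n_layers=self.n_layers,
                            n_heads=self.n_heads, max_len=self.max_len,
                            vocab_size=self.vocab_size,
                            projection_dim=self.projection_dim,
                            dropout=self.dropout, seed=self.seed)
        pre = PretrainConfig(batch_size=self.batch_size,
                             temperature=self.temperature,
                             learning_rate=self.learning_rate,
                             epochs=self.epochs,
                             augmentation=self.augmentation,
                             mask_fraction=self.mask_fraction,
                             seed=self.seed)
        return enc, pre

    def fit(self, X, y=None):
        smiles = _as_smiles_list(X)
        records = [SmilesRecord(smiles=s) for s in smiles]
        enc, pre = self._configs()
        self.model_, self.training_log_ = pretrain(records, enc, pre)
        self.vocab_ = self.model_.vocab
        self.loss_history_ = self.training_log_.losses
        self.n_features_out_ = (enc.projection_dim
                                if self.representation == "projected"
                                else enc.d_model)
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        return self.model_.embed_smiles(_as_smiles_list(X),
                                        representation=self.representation)

    def __sklearn_tags__(self):
        tags = super().__sklearn_tags__()
        tags.input_tags.string = True
        tags.no_validation = True
        return tags


class _FinetuneEstimator(BaseEstimator):
    """Shared fine-tuning machinery for the classifier/regressor."""

    _task_type: str
    _metric: str

    def __init__(self, encoder=None, d_model=64, n_layers=2, n_heads=8,
                 max_len=128, vocab_size=300, dropout=0.1,
                 learning_rate=1e-3, epochs=30, batch_size=32, patience=10,
                 freeze_encoder=False, representation="pooled",
                 valid_fraction=0.15, seed=0):
        self.encoder = encoder
        self.d_model = d_model
        self.n_layers = n_layers
        self.n_heads = n_heads
        self.max_len = max_len
        self.vocab_size = vocab_size
        self.dropout = dropout
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.patience = patience
        self.freeze_encoder = freeze_encoder
        self.representation = representation
        self.valid_fraction = valid_fraction
        self.seed = seed

    def _base_encoder(self, smiles: list[str]) -> SmilesEncoder:
        if self.encoder is not None:
            enc = self.encoder
            if isinstance(enc, ContrastiveSmilesEncoder):
                check_is_fitted(enc, "model_")
                enc = enc.model_
            if not isinstance(enc, SmilesEncoder):
                raise TypeError("encoder must be a fitted "
                                "ContrastiveSmilesEncoder or a SmilesEncoder")
            return enc
        # fresh random-initialized encoder (no pre-training): the
        # vocabulary is trained on the labeled SMILES themselves
        from .tokenizer import train_bpe
        vocab = train_bpe(smiles, vocab_size=self.vocab_size)
        cfg = EncoderConfig(d_model=self.d_model, n_layers=self.n_layers,
                            n_heads=self.n_heads, max_len=self.max_len,
                            vocab_size=self.vocab_size, dropout=self.dropout,
                            seed=self.seed)
        return SmilesEncoder(cfg, vocab=vocab)

    def fit(self, X, y):
        smiles = _as_smiles_list(X)
        y = np.asarray(y, dtype=np.float64)
        if y.ndim == 1:
            y = y[:, None]
        if len(smiles) != y.shape[0]:
            raise ValueError("X and y disagree in length")
        encoder = self._base_encoder(smiles)
        records = [SmilesRecord(smiles=s) for s in smiles]
        task_names = [f"task{i}" for i in range(y.shape[1])]
        dataset = LabeledDataset(records, y, task_names)
        vf = self.valid_fraction
        train, valid, _ = split_dataset(
            dataset, "random", (1.0 - vf, vf / 2, vf / 2), seed=self.seed)
        spec = TaskSpec(self._task_type, y.shape[1], self._metric)
        cfg = FinetuneConfig(learning_rate=self.learning_rate,
                             epochs=self.epochs, batch_size=self.batch_size,
                             patience=self.patience,
                             freeze_encoder=self.freeze_encoder,
                             representation=self.representation,
                             seed=self.seed)
        self.model_ = finetune(encoder, (train, valid, None), spec, cfg)
        self.n_tasks_ = y.shape[1]
        return self

    def _scores(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        records = [SmilesRecord(smiles=s) for s in _as_smiles_list(X)]
        return self.model_.predict(records)

    def __sklearn_tags__(self):
        tags = super().__sklearn_tags__()
        tags.input_tags.string = True
        tags.no_validation = True
        return tags


class SmilesClassifier(ClassifierMixin, _FinetuneEstimator):
    """Fine-tuned multi-task SMILES classifier (linear head, masked BCE)."""

    _task_type = "classification"
    _metric = "auc_roc"

    def fit(self, X, y):
        super().fit(X, y)
        self.classes_ = np.array([0.0, 1.0])
        return self

    def decision_function(self, X) -> np.ndarray:
        scores = self._scores(X)
        return scores[:, 0] if self.n_tasks_ == 1 else scores

    def predict_proba(self, X) -> np.ndarray:
        p = 1.0 / (1.0 + np.exp(-self._scores(X)))
        if self.n_tasks_ == 1:
            return np.column_stack([1.0 - p[:, 0], p[:, 0]])
        return p

    def predict(self, X) -> np.ndarray:
        scores = self._scores(X)
        pred = (scores > 0).astype(float)
        return pred[:, 0] if self.n_tasks_ == 1 else pred


class SmilesRegressor(RegressorMixin, _FinetuneEstimator):
    """Fine-tuned multi-task SMILES regressor (linear head, masked MSE on
    standardized targets; default metric RMSE)."""

    _task_type = "regression"
    _metric = "rmse"

    def predict(self, X) -> np.ndarray:
        pred = self._scores(X)
        return pred[:, 0] if self.n_tasks_ == 1 else pred
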