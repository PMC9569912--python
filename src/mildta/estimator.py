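"""Scikit-learn estimator facade over the full pipeline.

``MILBindingAffinityRegressor`` takes raw (SMILES, protein sequence) pairs
and a real-valued affinity target, fits the subword tokenizers and the
network end to end, and predicts affinities for new pairs.  It follows the
scikit-learn contract (get_params/set_params, fitted attributes with a
trailing underscore) so it composes with model-selection utilities, within
the limits of string-valued features.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from .model import FULL_SUBSET, DTABagModel
from .tokenization import UnigramTokenizer
from .training import EncodedPairs, TrainConfig, fit_model

__all__ = ["MILBindingAffinityRegressor"]


def _extract_strings(X) -> tuple[list[str], list[str]]:
    if isinstance(X, pd.DataFrame):
        missing = {"smiles", "sequence"} - set(X.columns)
        if missing:
            raise ValueError(f"X is missing columns {sorted(missing)}")
        return list(X["smiles"]), list(X["sequence"])
    arr = np.asarray(X, dtype=object)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError(
            "X must be a DataFrame with 'smiles'/'sequence' columns or an "
            "(n, 2) array of [smiles, sequence] strings"
        )
    return list(arr[:, 0]), list(arr[:, 1])


class MILBindingAffinityRegressor(RegressorMixin, BaseEstimator):
    """Drug-target affinity regressor with a private/public instance bag.

    Parameters default to the full-scale architecture (model width 128,
    two encoder layers, four attention heads, three gate blocks, scorer
    MLPs 1024-1024-512-1); desk-scale work passes smaller values.

    Parameters
    ----------
    d_model : model/feature width shared by encoders, CNN and MHCA.
    n_layers, n_heads, ffn_dim : transformer encoder stack shape.
    n_gate_blocks, kernel_size, dilation_rates : GatedCNN stack shape.
    scorer_hidden : hidden widths of each instance-scoring MLP.
    instance_subset : which instance families exist — any non-empty subset
        of {"private", "public_early", "public_late"}.
    drug_vocab_size, protein_vocab_size : unigram vocabulary sizes (the
        fitted size is capped by what the training strings admit and is
        floored at the alphabet size).
    drug_max_len, protein_max_len : token-sequence lengths after padding.
    learning_rate, betas, eps, weight_decay : AdamW settings.
    batch_size, max_epochs, patience : loop control; early stopping
        monitors validation MSE.
    validation_fraction : fraction of the training pairs held out for
        early stopping.
    random_state : seed for tokenizer fitting, initialization, shuffling
        and the internal validation split.

    Attributes
    ----------
    model_ : the fitted network.
    drug_tokenizer_, protein_tokenizer_ : fitted unigram tokenizers.
    history_ : per-epoch training record.
    fusion_weights_ : learned instance-fusion weights, in the order of
        ``model_.cfg.enabled_roles``.
    """

    def __init__(
        self,
        d_model: int = 128,
        n_layers: int = 2,
        n_heads: int = 4,
        ffn_dim: int | None = None,
        n_gate_blocks: int = 3,
        kernel_size: int = 3,
        dilation_rates: tuple[int, ...] = (1, 2, 4),
        scorer_hidden: tuple[int, ...] = (1024, 1024, 512),
        instance_subset: tuple[str, ...] = FULL_SUBSET,
        fusion_intercept: bool = False,
        drug_vocab_size: int = 900,
        protein_vocab_size: int = 10000,
        drug_max_len: int = 128,
        protein_max_len: int = 512,
        learning_rate: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
        batch_size: int = 64,
        max_epochs: int = 200,
        patience: int = 20,
        validation_fraction: float = 0.1,
        random_state: int = 0,
    ):
        self.d_model = d_model
        self.n_layers = n_layers
        self.n_heads = n_heads
        self.ffn_dim = ffn_dim
        self.n_gate_blocks = n_gate_blocks
        self.kernel_size = kernel_size
        self.dilation_rates = dilation_rates
        self.scorer_hidden = scorer_hidden
        self.instance_subset = instance_subset
        self.fusion_intercept = fusion_intercept
        self.drug_vocab_size = drug_vocab_size
        self.protein_vocab_size = protein_vocab_size
        self.drug_max_len = drug_max_len
        self.protein_max_len = protein_max_len
        self.learning_rate = learning_rate
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    # -- internals ------------------------------------------------------------
    def _train_config(self) -> TrainConfig:
        return TrainConfig(
            learning_rate=self.learning_rate,
            betas=tuple(self.betas),
            eps=self.eps,
            weight_decay=self.weight_decay,
            batch_size=self.batch_size,
            max_epochs=self.max_epochs,
            patience=self.patience,
            instance_subset=tuple(self.instance_subset),
            seed=self.random_state,
            drug_vocab_size=self.drug_vocab_size,
            protein_vocab_size=self.protein_vocab_size,
            arch={
                "d_model": self.d_model,
                "n_layers": self.n_layers,
                "n_heads": self.n_heads,
                "ffn_dim": self.ffn_dim,
                "n_gate_blocks": self.n_gate_blocks,
                "kernel_size": self.kernel_size,
                "dilation_rates": list(self.dilation_rates),
                "scorer_hidden": list(self.scorer_hidden),
                "fusion_intercept": self.fusion_intercept,
                "drug_max_len": self.drug_max_len,
                "protein_max_len": self.protein_max_len,
            },
        )

    def _encode(self, smiles, sequences, y=None) -> EncodedPairs:
        d_ids, d_mask = [], []
        p_ids, p_mask = [], []
        d_cache, p_cache = {}, {}
        for s in smiles:
            if s not in d_cache:
                d_cache[s] = self.drug_tokenizer_.encode(s, self.drug_max_len)
            d_ids.append(d_cache[s].ids)
            d_mask.append(d_cache[s].mask)
        for s in sequences:
            if s not in p_cache:
                p_cache[s] = self.protein_tokenizer_.encode(s, self.protein_max_len)
            p_ids.append(p_cache[s].ids)
            p_mask.append(p_cache[s].mask)
        return EncodedPairs(
            np.stack(d_ids), np.stack(d_mask), np.stack(p_ids), np.stack(p_mask),
            np.zeros(len(smiles)) if y is None else np.asarray(y, dtype=float),
        )

    # -- sklearn API ----------------------------------------------------------
    def fit(self, X, y):
        smiles, sequences = _extract_strings(X)
        y = np.asarray(y, dtype=float).ravel()
        if len(y) != len(smiles):
            raise ValueError("X and y length mismatch")
        if len(y) < 2:
            raise ValueError("need at least two training pairs")
        cfg = self._train_config()

        def fit_tok(corpus, requested):
            corpus = sorted(set(corpus))
            n_chars = len({c for s in corpus for c in s})
            return UnigramTokenizer(
                vocab_size=max(requested, n_chars), seed=self.random_state
            ).fit(corpus)

        self.drug_tokenizer_ = fit_tok(smiles, self.drug_vocab_size)
        self.protein_tokenizer_ = fit_tok(sequences, self.protein_vocab_size)

        data = self._encode(smiles, sequences, y)
        rng = np.random.default_rng(self.random_state)
        n = len(y)
        n_val = int(round(self.validation_fraction * n))
        perm = rng.permutation(n)
        val_idx, train_idx = perm[:n_val], perm[n_val:]
        model_cfg = cfg.model_config(
            self.drug_tokenizer_.n_ids, self.protein_tokenizer_.n_ids
        )
        self.model_ = DTABagModel(model_cfg, rng=np.random.default_rng(self.random_state))
        self.history_ = fit_model(
            self.model_,
            data.take(train_idx),
            data.take(val_idx) if n_val else None,
            cfg,
        )
        self.fusion_weights_ = self.model_.head.fusion_weights.data.copy()
        self.n_features_in_ = 2
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "model_"):
            raise RuntimeError("estimator is not fitted")
        smiles, sequences = _extract_strings(X)
        data = self._encode(smiles, sequences)
        return self.model_.predict_arrays(
            data.d_ids, data.d_mask, data.p_ids, data.p_mask,
            batch_size=self.batch_size,
        )
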