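"""Training, evaluation and ablation orchestration.

The network is optimized with AdamW (learning rate 1e-3, betas (0.9, 0.999),
eps 1e-8 by default) on the mean-squared-error loss, with early stopping on
the validation MSE.  Everything is seeded: tokenizer fitting, weight
initialization, batch shuffling and the splits that feed the loop, so a run
is fully reproducible from (seed, config, data) on a single CPU thread.

Tokenizers are fitted on the training-partition entity strings only, so no
test-set sequence information reaches the model through the vocabulary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from ._nn import AdamW
from .data import DTDataset, SplitAssignment
from .metrics import MetricsReport, compute_report
from .mil import mse_loss_tensor
from .model import FULL_SUBSET, DTABagModel, ModelConfig
from .tokenization import UnigramTokenizer

__all__ = [
    "TrainConfig",
    "TrainingHistory",
    "Checkpoint",
    "EncodedPairs",
    "encode_pairs",
    "fit_model",
    "train",
    "evaluate",
    "ablate",
    "ABLATION_CONFIGS",
]

# the seven instance-subset configurations of the ablation design
ABLATION_CONFIGS: list[tuple[str, ...]] = [
    ("private",),
    ("private", "public_late"),
    ("private", "public_early"),
    ("public_early",),
    ("public_late",),
    ("public_late", "public_early"),
    ("private", "public_late", "public_early"),
]


@dataclass
class TrainConfig:
    """Optimizer, loop and architecture settings for one training run."""

    learning_rate: float = 1e-3
    betas: tuple[float, float] = (0.9, 0.999)
    eps: float = 1e-8
    weight_decay: float = 0.0
    batch_size: int = 64
    max_epochs: int = 200
    patience: int = 20
    min_delta: float = 1e-6  # smaller val-loss improvements do not reset patience
    instance_subset: tuple[str, ...] = FULL_SUBSET
    seed: int = 0
    drug_vocab_size: int = 900
    protein_vocab_size: int = 10000
    arch: dict = field(default_factory=dict)  # ModelConfig overrides

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if not self.instance_subset:
            raise ValueError("instance_subset must be non-empty")
        self.instance_subset = tuple(self.instance_subset)
        self.betas = tuple(self.betas)

    def model_config(self, n_drug_ids: int, n_protein_ids: int) -> ModelConfig:
        return ModelConfig.from_dict(
            {
                "n_drug_ids": n_drug_ids,
                "n_protein_ids": n_protein_ids,
                "instance_subset": list(self.instance_subset),
                **self.arch,
            }
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TrainConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["betas"] = list(self.betas)
        d["instance_subset"] = list(self.instance_subset)
        Path(path).write_text(yaml.safe_dump(d))


@dataclass
class TrainingHistory:
    """Per-epoch record of one run."""

    epochs: list[dict] = field(default_factory=list)
    best_epoch: int = -1
    stopping_reason: str = ""

    @property
    def best_val_loss(self) -> float:
        return min(e["val_loss"] for e in self.epochs)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.epochs)


@dataclass
class EncodedPairs:
    """Token-id arrays for a list of pairs, plus labels."""

    d_ids: np.ndarray
    d_mask: np.ndarray
    p_ids: np.ndarray
    p_mask: np.ndarray
    y: np.ndarray

    def __len__(self) -> int:
        return len(self.y)

    def take(self, idx) -> "EncodedPairs":
        idx = np.asarray(idx)
        return EncodedPairs(
            self.d_ids[idx], self.d_mask[idx], self.p_ids[idx], self.p_mask[idx],
            self.y[idx],
        )


def encode_pairs(
    ds: DTDataset,
    indices,
    drug_tok: UnigramTokenizer,
    protein_tok: UnigramTokenizer,
    drug_max_len: int,
    protein_max_len: int,
) -> EncodedPairs:
    """Tokenize the pairs at `indices`, caching per-entity encodings."""
    d_cache: dict[str, tuple] = {}
    p_cache: dict[str, tuple] = {}
    rows_d, rows_dm, rows_p, rows_pm, ys = [], [], [], [], []
    for i in indices:
        d, t, y = ds.pairs[i]
        if d not in d_cache:
            e = drug_tok.encode(ds.drugs[d], drug_max_len)
            d_cache[d] = (e.ids, e.mask)
        if t not in p_cache:
            e = protein_tok.encode(ds.targets[t], protein_max_len)
            p_cache[t] = (e.ids, e.mask)
        rows_d.append(d_cache[d][0])
        rows_dm.append(d_cache[d][1])
        rows_p.append(p_cache[t][0])
        rows_pm.append(p_cache[t][1])
        ys.append(y)
    return EncodedPairs(
        np.stack(rows_d), np.stack(rows_dm), np.stack(rows_p), np.stack(rows_pm),
        np.asarray(ys, dtype=float),
    )


def fit_model(
    model: DTABagModel,
    train_data: EncodedPairs,
    val_data: EncodedPairs | None,
    cfg: TrainConfig,
    with_val_metrics: bool = True,
) -> TrainingHistory:
    """Minimize the MSE loss with AdamW and early stopping on validation MSE.

    The model is left holding the best-validation-loss parameters.  When no
    validation set is given, early stopping monitors the training loss.
    """
    rng = np.random.default_rng(cfg.seed)
    opt = AdamW(
        model.parameters(),
        lr=cfg.learning_rate,
        betas=cfg.betas,
        eps=cfg.eps,
        weight_decay=cfg.weight_decay,
    )
    history = TrainingHistory()
    best_loss = np.inf
    best_state = model.state_dict()
    stale = 0
    n = len(train_data)
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        batch_losses = []
        for start in range(0, n, cfg.batch_size):
            batch = train_data.take(order[start : start + cfg.batch_size])
            opt.zero_grad()
            y_hat, _ = model(batch.d_ids, batch.d_mask, batch.p_ids, batch.p_mask)
            loss = mse_loss_tensor(y_hat, batch.y)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: loss={loss.data}; "
                    "reduce the learning rate or check the input scale"
                )
            loss.backward()
            opt.step()
            batch_losses.append(float(loss.data))
        row = {"epoch": epoch, "train_loss": float(np.mean(batch_losses))}
        if val_data is not None and len(val_data):
            val_pred = model.predict_arrays(
                val_data.d_ids, val_data.d_mask, val_data.p_ids, val_data.p_mask,
                batch_size=cfg.batch_size,
            )
            row["val_loss"] = float(np.mean((val_data.y - val_pred) ** 2))
            if with_val_metrics:
                report = compute_report(val_pred, val_data.y)
                row["val_ci"] = report.ci
                row["val_r"] = report.pearson_r
        else:
            row["val_loss"] = row["train_loss"]
        history.epochs.append(row)
        if row["val_loss"] < best_loss - cfg.min_delta:
            best_loss = row["val_loss"]
            best_state = model.state_dict()
            history.best_epoch = epoch
            stale = 0
        else:
            stale += 1
            if stale >= cfg.patience:
                history.stopping_reason = "patience_exhausted"
                break
    if not history.stopping_reason:
        history.stopping_reason = "max_epochs"
    model.load_state_dict(best_state)
    return history


@dataclass
class Checkpoint:
    """Everything needed to re-run a trained model deterministically."""

    model_config: ModelConfig
    state: dict[str, np.ndarray]
    drug_tokenizer: UnigramTokenizer
    protein_tokenizer: UnigramTokenizer
    train_config: TrainConfig | None = None

    def build_model(self) -> DTABagModel:
        model = DTABagModel(self.model_config, rng=0)
        model.load_state_dict(self.state)
        return model

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        (path / "model_config.json").write_text(
            json.dumps(self.model_config.to_dict())
        )
        np.savez(path / "weights.npz", **self.state)
        self.drug_tokenizer.save(path / "drug_tokenizer.json")
        self.protein_tokenizer.save(path / "protein_tokenizer.json")
        if self.train_config is not None:
            self.train_config.to_yaml(path / "train_config.yaml")

    @classmethod
    def load(cls, path: str | Path) -> "Checkpoint":
        path = Path(path)
        model_config = ModelConfig.from_dict(
            json.loads((path / "model_config.json").read_text())
        )
        with np.load(path / "weights.npz") as npz:
            state = {k: npz[k] for k in npz.files}
        train_config = None
        if (path / "train_config.yaml").exists():
            train_config = TrainConfig.from_yaml(path / "train_config.yaml")
        return cls(
            model_config=model_config,
            state=state,
            drug_tokenizer=UnigramTokenizer.load(path / "drug_tokenizer.json"),
            protein_tokenizer=UnigramTokenizer.load(path / "protein_tokenizer.json"),
            train_config=train_config,
        )


def _fit_tokenizers(
    ds: DTDataset, split: SplitAssignment, cfg: TrainConfig
) -> tuple[UnigramTokenizer, UnigramTokenizer]:
    train_val = list(split.train) + list(split.val)
    drug_corpus = sorted({ds.drugs[ds.pairs[i][0]] for i in train_val})
    prot_corpus = sorted({ds.targets[ds.pairs[i][1]] for i in train_val})

    def fit_one(corpus, requested):
        n_chars = len({c for s in corpus for c in s})
        size = max(requested, n_chars)
        return UnigramTokenizer(vocab_size=size, seed=cfg.seed).fit(corpus)

    return fit_one(drug_corpus, cfg.drug_vocab_size), fit_one(
        prot_corpus, cfg.protein_vocab_size
    )


def train(
    config: TrainConfig, split: SplitAssignment, ds: DTDataset
) -> tuple[Checkpoint, TrainingHistory]:
    """Fit tokenizers and the network on one split of one dataset."""
    drug_tok, prot_tok = _fit_tokenizers(ds, split, config)
    model_cfg = config.model_config(drug_tok.n_ids, prot_tok.n_ids)
    model = DTABagModel(model_cfg, rng=np.random.default_rng(config.seed))
    enc = lambda idx: encode_pairs(
        ds, idx, drug_tok, prot_tok, model_cfg.drug_max_len, model_cfg.protein_max_len
    )
    history = fit_model(model, enc(split.train), enc(split.val), config)
    checkpoint = Checkpoint(
        model_config=model_cfg,
        state=model.state_dict(),
        drug_tokenizer=drug_tok,
        protein_tokenizer=prot_tok,
        train_config=config,
    )
    return checkpoint, history


def evaluate(
    checkpoint: Checkpoint, indices, ds: DTDataset, batch_size: int = 64
) -> MetricsReport:
    """Deterministic forward pass over one split partition, all metrics."""
    indices = list(indices)
    if not indices:
        raise ValueError("cannot evaluate an empty partition")
    cfg = checkpoint.model_config
    data = encode_pairs(
        ds, indices, checkpoint.drug_tokenizer, checkpoint.protein_tokenizer,
        cfg.drug_max_len, cfg.protein_max_len,
    )
    model = checkpoint.build_model()
    pred = model.predict_arrays(
        data.d_ids, data.d_mask, data.p_ids, data.p_mask, batch_size=batch_size
    )
    return compute_report(pred, data.y)


def ablate(base_config: TrainConfig, ds: DTDataset, split: SplitAssignment):
    """Run the seven instance-subset configurations and collect metrics.

    Each configuration retrains from scratch (fusion weights included) with
    the base seed and settings, then evaluates on the test partition.
    Returns a pandas DataFrame with one row per configuration.
    """
    import copy

    import pandas as pd

    rows = []
    for subset in ABLATION_CONFIGS:
        cfg = copy.deepcopy(base_config)
        cfg.instance_subset = subset
        checkpoint, history = train(cfg, split, ds)
        report = evaluate(checkpoint, split.test, ds)
        rows.append(
            {
                "private": "private" in subset,
                "public_late": "public_late" in subset,
                "public_early": "public_early" in subset,
                "n_instances": len(checkpoint.model_config.enabled_roles),
                "ci": report.ci,
                "mse": report.mse,
                "r": report.pearson_r,
                "rm2": report.rm2,
                "best_epoch": history.best_epoch,
            }
        )
    return pd.DataFrame(rows)
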