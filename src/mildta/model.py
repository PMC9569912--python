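"""The end-to-end affinity network: encoders, instance generator, MIL head.

A batch of tokenized drug-target pairs flows through two independent
transformer encoder stacks, the private/public instance generator, and the
multiple-instance regression head, producing one predicted affinity per
pair together with the per-instance scores that the learned fusion weights
combine.

Which instances exist is governed by ``instance_subset``: ``private`` (the
pooled drug GatedCNN feature), ``public_early`` (the two cross-attention
features) and ``public_late`` (the concatenated private drug and protein
features).  The full model enables all three.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from ._autodiff import Tensor, concat
from ._nn import Module
from .encoder import EncoderConfig, TransformerEncoder
from .instances import GatedCnnConfig, InstanceGenerator
from .mil import INSTANCE_ORDER, MilHead

__all__ = ["ModelConfig", "SUBSET_ROLES", "DTABagModel"]

# instance-subset components -> instance roles
SUBSET_ROLES = {
    "private": ("private_d",),
    "public_early": ("public_dp", "public_pd"),
    "public_late": ("public_concat",),
}
FULL_SUBSET = ("private", "public_early", "public_late")


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters (defaults are the full-scale values)."""

    n_drug_ids: int = 902
    n_protein_ids: int = 10002
    drug_max_len: int = 128
    protein_max_len: int = 512
    d_model: int = 128
    n_layers: int = 2
    n_heads: int = 4
    ffn_dim: int | None = None
    n_gate_blocks: int = 3
    kernel_size: int = 3
    dilation_rates: tuple[int, ...] = (1, 2, 4)
    scorer_hidden: tuple[int, ...] = (1024, 1024, 512)
    instance_subset: tuple[str, ...] = FULL_SUBSET
    fusion_intercept: bool = False

    def __post_init__(self):
        unknown = set(self.instance_subset) - set(SUBSET_ROLES)
        if unknown:
            raise ValueError(f"unknown instance subset entries: {sorted(unknown)}")
        if not self.instance_subset:
            raise ValueError("instance_subset must be non-empty")

    @property
    def encoder_config(self) -> EncoderConfig:
        return EncoderConfig(
            n_layers=self.n_layers,
            n_heads=self.n_heads,
            d_model=self.d_model,
            ffn_dim=self.ffn_dim,
        )

    @property
    def cnn_config(self) -> GatedCnnConfig:
        return GatedCnnConfig(
            n_blocks=self.n_gate_blocks,
            kernel_size=self.kernel_size,
            n_filters=self.d_model,
            dilation_rates=tuple(self.dilation_rates)[: self.n_gate_blocks],
        )

    @property
    def enabled_roles(self) -> tuple[str, ...]:
        roles = {r for s in self.instance_subset for r in SUBSET_ROLES[s]}
        return tuple(r for r in INSTANCE_ORDER if r in roles)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["dilation_rates"] = list(self.dilation_rates)
        d["scorer_hidden"] = list(self.scorer_hidden)
        d["instance_subset"] = list(self.instance_subset)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        for key in ("dilation_rates", "scorer_hidden", "instance_subset"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


class DTABagModel(Module):
    """Full network; forward maps token-id batches to affinities."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator | int = 0):
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        self.cfg = cfg
        enc = cfg.encoder_config
        self.drug_encoder = TransformerEncoder(
            cfg.n_drug_ids, cfg.drug_max_len, enc, rng
        )
        self.protein_encoder = TransformerEncoder(
            cfg.n_protein_ids, cfg.protein_max_len, enc, rng
        )
        self.instance_gen = InstanceGenerator(enc, cfg.cnn_config, rng)
        self.head = MilHead(
            cfg.d_model,
            tuple(cfg.scorer_hidden),
            rng,
            enabled=cfg.enabled_roles,
            intercept=cfg.fusion_intercept,
        )

    def instances(
        self,
        d_ids: np.ndarray,
        d_mask: np.ndarray,
        p_ids: np.ndarray,
        p_mask: np.ndarray,
    ) -> dict[str, Tensor]:
        """Compute only the instance tensors the configuration enables."""
        roles = set(self.cfg.enabled_roles)
        h_d = self.drug_encoder(d_ids, d_mask)
        h_p = self.protein_encoder(p_ids, p_mask)
        out: dict[str, Tensor] = {}
        gen = self.instance_gen
        if roles & {"private_d", "public_concat"}:
            private_d = gen.drug_cnn(h_d, d_mask)
            if "private_d" in roles:
                out["private_d"] = private_d
            if "public_concat" in roles:
                private_p = gen.protein_cnn(h_p, p_mask)
                out["public_concat"] = concat([private_d, private_p], axis=-1)
        if roles & {"public_dp", "public_pd"}:
            public_dp, public_pd = gen.public_early(h_d, d_mask, h_p, p_mask)
            out["public_dp"] = public_dp
            out["public_pd"] = public_pd
        return out

    def __call__(
        self,
        d_ids: np.ndarray,
        d_mask: np.ndarray,
        p_ids: np.ndarray,
        p_mask: np.ndarray,
    ) -> tuple[Tensor, Tensor]:
        """Returns (y_hat, instance_scores) for the batch."""
        return self.head(self.instances(d_ids, d_mask, p_ids, p_mask))

    def predict_arrays(
        self,
        d_ids: np.ndarray,
        d_mask: np.ndarray,
        p_ids: np.ndarray,
        p_mask: np.ndarray,
        batch_size: int = 64,
    ) -> np.ndarray:
        """Deterministic forward pass in batches; returns plain predictions."""
        out = []
        for start in range(0, len(d_ids), batch_size):
            sl = slice(start, start + batch_size)
            y_hat, _ = self(d_ids[sl], d_mask[sl], p_ids[sl], p_mask[sl])
            out.append(y_hat.data)
        return np.concatenate(out)
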