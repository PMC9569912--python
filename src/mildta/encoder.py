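"""Transformer sequence encoders for tokenized drugs and proteins.

Each stream (drug SMILES, protein sequence) is embedded, summed with a
sinusoidal positional encoding, and passed through a stack of post-norm
transformer layers: multi-head scaled dot-product self-attention, then a
position-wise feed-forward network, each wrapped as
``ResiNorm(f, x) = LayerNorm(x + f(x))``.  The two streams share nothing.

Padding positions are excluded from the attention softmax, so the content
of padded positions can never influence an unmasked output row.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor
from ._nn import Embedding, LayerNorm, Linear, Module

__all__ = [
    "EncoderConfig",
    "positional_encoding",
    "attention",
    "self_attention_head",
    "MultiHeadAttention",
    "EncoderLayer",
    "TransformerEncoder",
    "encode_pair",
]

_MASK_NEG = 1e9


@dataclass(frozen=True)
class EncoderConfig:
    """Architecture of one transformer encoder stack."""

    n_layers: int = 2
    n_heads: int = 4
    d_model: int = 128
    ffn_dim: int | None = None  # None -> 4 * d_model

    def __post_init__(self):
        if self.n_layers < 0 or self.n_heads < 1 or self.d_model < 1:
            raise ValueError("dimensions must be positive (n_layers may be 0)")
        if self.d_model % self.n_heads:
            raise ValueError(
                f"d_model={self.d_model} not divisible by n_heads={self.n_heads}"
            )

    @property
    def head_dim(self) -> int:
        return self.d_model // self.n_heads

    @property
    def ffn_width(self) -> int:
        return 4 * self.d_model if self.ffn_dim is None else self.ffn_dim


def positional_encoding(T: int, d_model: int) -> np.ndarray:
    """Sinusoidal positional code: PE[p, 2i] = sin(p / 10000^(2i/d)),
    PE[p, 2i+1] = cos(p / 10000^(2i/d))."""
    if d_model % 2:
        raise ValueError("d_model must be even for the sin/cos interleaving")
    if T < 1 or d_model < 1:
        raise ValueError("T and d_model must be positive")
    pos = np.arange(T)[:, None]
    i2 = np.arange(0, d_model, 2)
    angle = pos / np.power(10000.0, i2 / d_model)
    pe = np.empty((T, d_model))
    pe[:, 0::2] = np.sin(angle)
    pe[:, 1::2] = np.cos(angle)
    return pe


def attention(
    q: Tensor, k: Tensor, v: Tensor, kv_mask: np.ndarray | None, scale: float
) -> Tensor:
    """softmax(q kᵀ · scale) v with masked key positions excluded.

    Shapes: q (..., Tq, d), k/v (..., Tk, d), kv_mask broadcastable to
    (..., Tq, Tk) or a (Tk,)/( …, Tk) key mask; True marks real positions.
    """
    scores = (q @ k.swapaxes(-1, -2)) * scale
    if kv_mask is not None:
        kv_mask = np.asarray(kv_mask, dtype=bool)
        if not kv_mask.any(axis=-1).all():
            raise ValueError("attention over an entirely masked key sequence")
        bias = np.where(kv_mask, 0.0, -_MASK_NEG)
        # broadcast a key mask (..., Tk) over query positions
        scores = scores + bias.reshape(bias.shape[:-1] + (1, bias.shape[-1]))
    return scores.softmax(axis=-1) @ v


def self_attention_head(
    x: np.ndarray,
    weights: tuple[np.ndarray, np.ndarray, np.ndarray],
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Single self-attention head on a T×d input with explicit projections.

    Output row t is the softmax(QKᵀ/√d)-weighted sum of value rows, with
    masked key positions receiving zero weight.
    """
    wq, wk, wv = (Tensor(w) for w in weights)
    xt = Tensor(np.asarray(x, dtype=float))
    d = wq.data.shape[1]
    out = attention(xt @ wq, xt @ wk, xt @ wv, mask, 1.0 / np.sqrt(d))
    return out.data


class MultiHeadAttention(Module):
    """h parallel heads, concatenated and mixed by an output projection.

    Serves both self-attention (q_src is kv_src) and cross-attention
    (queries from one stream, keys/values from the other).
    """

    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator):
        d = cfg.d_model
        self.n_heads = cfg.n_heads
        self.head_dim = cfg.head_dim
        self.wq = Linear(d, d, rng, bias=False)
        self.wk = Linear(d, d, rng, bias=False)
        self.wv = Linear(d, d, rng, bias=False)
        self.wo = Linear(d, d, rng, bias=False)

    def _split(self, x: Tensor) -> Tensor:
        B, T, D = x.shape
        return x.reshape(B, T, self.n_heads, self.head_dim).swapaxes(1, 2)

    def __call__(
        self, q_src: Tensor, kv_src: Tensor, kv_mask: np.ndarray | None
    ) -> Tensor:
        q = self._split(self.wq(q_src))
        k = self._split(self.wk(kv_src))
        v = self._split(self.wv(kv_src))
        if kv_mask is not None:
            kv_mask = np.asarray(kv_mask, dtype=bool)[:, None, :]  # (B, 1, Tk)
        out = attention(q, k, v, kv_mask, 1.0 / np.sqrt(self.head_dim))
        B, _, Tq, _ = out.shape
        return self.wo(out.swapaxes(1, 2).reshape(B, Tq, self.n_heads * self.head_dim))


class EncoderLayer(Module):
    """Post-norm transformer layer:
    ``ResiNorm(FFN, ResiNorm(MultiHead, x))``."""

    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator):
        self.attn = MultiHeadAttention(cfg, rng)
        self.norm1 = LayerNorm(cfg.d_model)
        self.ffn1 = Linear(cfg.d_model, cfg.ffn_width, rng)
        self.ffn2 = Linear(cfg.ffn_width, cfg.d_model, rng)
        self.norm2 = LayerNorm(cfg.d_model)

    def __call__(self, x: Tensor, mask: np.ndarray | None) -> Tensor:
        if not np.isfinite(x.data).all():
            raise ValueError("non-finite encoder input")
        h = self.norm1(x + self.attn(x, x, mask))
        return self.norm2(h + self.ffn2(self.ffn1(h).relu()))


class TransformerEncoder(Module):
    """Embedding + positional encoding + a stack of encoder layers."""

    def __init__(
        self,
        n_ids: int,
        max_len: int,
        cfg: EncoderConfig,
        rng: np.random.Generator,
    ):
        self.n_ids = n_ids
        self.cfg = cfg
        self.embed = Embedding(n_ids, cfg.d_model, rng)
        self.pos = positional_encoding(max_len, cfg.d_model)
        self.layers = [EncoderLayer(cfg, rng) for _ in range(cfg.n_layers)]

    def __call__(self, ids: np.ndarray, mask: np.ndarray) -> Tensor:
        ids = np.asarray(ids, dtype=np.int64)
        if ids.min() < 0 or ids.max() >= self.n_ids:
            raise ValueError(
                f"token id out of range [0, {self.n_ids}): "
                f"[{ids.min()}, {ids.max()}]"
            )
        T = ids.shape[-1]
        h = self.embed(ids) + self.pos[:T]
        for layer in self.layers:
            h = layer(h, mask)
        return h


def encode_pair(drug, protein, drug_encoder, protein_encoder):
    """Run both streams through their own (independent) encoder stacks.

    `drug` and `protein` are TokenSequence objects or (ids, mask) pairs;
    returns the two context matrices as (values, mask) with values of shape
    max_len × d_model.
    """
    def unpack(x):
        if hasattr(x, "ids"):
            return x.ids, x.mask
        return x

    d_ids, d_mask = unpack(drug)
    p_ids, p_mask = unpack(protein)
    h_d = drug_encoder(d_ids[None, :], d_mask[None, :])
    h_p = protein_encoder(p_ids[None, :], p_mask[None, :])
    return (h_d.data[0], np.asarray(d_mask, bool)), (h_p.data[0], np.asarray(p_mask, bool))
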