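"""Construction of the four multiple-instance feature vectors of a bag.

A drug-target pair (the MIL "bag") yields four instances:

* ``private_d`` — the drug context passed through a residual dilated
  gated-convolution stack and globally max-pooled; this simulates a
  ligand-based predictor that sees only the compound;
* ``public_dp`` / ``public_pd`` — early-fusion interaction features from
  multi-head cross-attention (drug queries over protein keys/values, and
  the reverse), max-pooled;
* ``public_concat`` — late fusion: the concatenation of the pooled drug
  and protein private features.

The gated convolution follows the GatedCNN pattern: a causal dilated 1-D
convolution doubles the channel count, the result is split into a content
half and a gate half, and the content is multiplied by the sigmoid of the
gate; layer normalization is applied, then a residual connection adds the
block input.  Dilation rates default to (1, 2, 4), growing the receptive
field exponentially.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor, concat, where
from ._nn import LayerNorm, Module
from .encoder import EncoderConfig, MultiHeadAttention

__all__ = [
    "GatedCnnConfig",
    "InstanceSet",
    "dilated_conv_1d",
    "masked_global_max_pool",
    "DilatedConv1d",
    "GateBlock",
    "GatedCnn",
    "CrossAttentionBlock",
    "InstanceGenerator",
]

_POOL_NEG = 1e30


@dataclass(frozen=True)
class GatedCnnConfig:
    """Residual dilated GatedCNN stack configuration."""

    n_blocks: int = 3
    kernel_size: int = 3
    n_filters: int = 128
    dilation_rates: tuple[int, ...] = (1, 2, 4)

    def __post_init__(self):
        if self.n_blocks < 1 or self.kernel_size < 1 or self.n_filters < 1:
            raise ValueError("n_blocks, kernel_size and n_filters must be positive")
        if len(self.dilation_rates) != self.n_blocks:
            raise ValueError("need one dilation rate per block")
        if any(d < 1 for d in self.dilation_rates):
            raise ValueError("dilation rates must be >= 1")


@dataclass(frozen=True)
class InstanceSet:
    """The four instance vectors of one bag (fixed order)."""

    public_dp: np.ndarray  # drug->protein cross-attention, pooled; length m
    public_pd: np.ndarray  # protein->drug cross-attention, pooled; length m
    public_concat: np.ndarray  # {private_d, private_p}; length 2m
    private_d: np.ndarray  # pooled drug GatedCNN feature; length m

    def __post_init__(self):
        for v in (self.public_dp, self.public_pd, self.public_concat, self.private_d):
            if not np.isfinite(v).all():
                raise ValueError("non-finite instance vector")
        m = self.private_d.shape[-1]
        if self.public_concat.shape[-1] != 2 * m:
            raise ValueError("public_concat must be twice the private width")

    def __len__(self) -> int:  # bag cardinality
        return 4

    def as_list(self) -> list[np.ndarray]:
        return [self.public_dp, self.public_pd, self.public_concat, self.private_d]


def dilated_conv_1d(x, f, d: int) -> np.ndarray:
    """Causal dilated 1-D convolution on a scalar sequence.

    Output position s is Σ_{i=0}^{k−1} f(i) · x_{s−d·i}; indices before the
    start of the sequence contribute zero (left zero-padding), so the output
    has the input's length and position s never looks forward.
    """
    x = np.asarray(x, dtype=float)
    f = np.asarray(f, dtype=float)
    if f.ndim != 1 or x.ndim != 1:
        raise ValueError("dilated_conv_1d operates on 1-D sequences")
    if d < 1:
        raise ValueError("dilation rate must be >= 1")
    out = np.zeros_like(x)
    for i, fi in enumerate(f):
        shift = d * i
        if shift < len(x):
            out[shift:] += fi * x[: len(x) - shift]
    return out


def masked_global_max_pool(x: Tensor, mask: np.ndarray) -> Tensor:
    """Per-channel max over unmasked sequence positions.

    x: (B, T, C); mask: (B, T) boolean, True = real position.  Raises if any
    row has no unmasked position.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any(axis=-1).all():
        raise ValueError("global max pooling over an entirely masked sequence")
    guarded = where(mask[..., None], x, Tensor(-_POOL_NEG))
    return guarded.max(axis=-2)


class DilatedConv1d(Module):
    """Causal dilated convolution mapping (B, T, C_in) -> (B, T, C_out)."""

    def __init__(
        self, c_in: int, c_out: int, kernel_size: int, dilation: int,
        rng: np.random.Generator,
    ):
        bound = 1.0 / np.sqrt(c_in * kernel_size)
        self.weight = Tensor(
            rng.uniform(-bound, bound, size=(kernel_size, c_in, c_out)),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(c_out), requires_grad=True)
        self.kernel_size = kernel_size
        self.dilation = dilation

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.weight[0]
        for i in range(1, self.kernel_size):
            out = out + x.time_shift(self.dilation * i) @ self.weight[i]
        return out + self.bias


class GateBlock(Module):
    """One gated-convolution block with layer norm and a residual add.

    The convolution emits 2C channels which are split into a content half
    H_l and a gate half H_r; the block computes
    ``LayerNorm(H_l ⊗ σ(H_r)) + x``.
    """

    def __init__(
        self, channels: int, kernel_size: int, dilation: int,
        rng: np.random.Generator,
    ):
        self.conv = DilatedConv1d(channels, 2 * channels, kernel_size, dilation, rng)
        self.norm = LayerNorm(channels)
        self.channels = channels

    def __call__(self, x: Tensor) -> Tensor:
        h = self.conv(x)
        if h.shape[-1] % 2:
            raise ValueError("gate block convolution must emit an even channel count")
        h_l = h[..., : self.channels]
        h_r = h[..., self.channels :]
        gated = h_l * h_r.sigmoid()
        return self.norm(gated) + x


class GatedCnn(Module):
    """Residual dilated GatedCNN stack followed by masked global max pool."""

    def __init__(self, cfg: GatedCnnConfig, d_model: int, rng: np.random.Generator):
        if cfg.n_filters != d_model:
            raise ValueError(
                "n_filters must equal the encoder model width for the "
                f"residual connection ({cfg.n_filters} != {d_model})"
            )
        self.blocks = [
            GateBlock(d_model, cfg.kernel_size, d, rng) for d in cfg.dilation_rates
        ]

    def features(self, x: Tensor) -> Tensor:
        for block in self.blocks:
            x = block(x)
        return x

    def __call__(self, x: Tensor, mask: np.ndarray) -> Tensor:
        return masked_global_max_pool(self.features(x), mask)


class CrossAttentionBlock(Module):
    """MHCA: queries from X1, keys/values from X2, residual add of X1.

    ``Z = X1 + MultiHead(Q=X1 W, K=X2 W, V=X2 W)`` with h parallel heads
    concatenated and mixed by an output projection; key positions padded in
    X2 are excluded from the softmax.
    """

    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator):
        self.mha = MultiHeadAttention(cfg, rng)

    def __call__(self, x1: Tensor, x2: Tensor, x2_mask: np.ndarray | None) -> Tensor:
        return x1 + self.mha(x1, x2, x2_mask)


class InstanceGenerator(Module):
    """Builds all four instances from the two context matrices."""

    def __init__(
        self,
        enc_cfg: EncoderConfig,
        cnn_cfg: GatedCnnConfig,
        rng: np.random.Generator,
    ):
        self.drug_cnn = GatedCnn(cnn_cfg, enc_cfg.d_model, rng)
        self.protein_cnn = GatedCnn(cnn_cfg, enc_cfg.d_model, rng)
        self.mhca_dp = CrossAttentionBlock(enc_cfg, rng)
        self.mhca_pd = CrossAttentionBlock(enc_cfg, rng)

    def private_instances(
        self, h_drug: Tensor, d_mask: np.ndarray, h_prot: Tensor, p_mask: np.ndarray
    ) -> tuple[Tensor, Tensor]:
        """Pooled GatedCNN features for both streams; only the drug one is
        used as the private instance, the protein one feeds the late-fusion
        concatenation."""
        return self.drug_cnn(h_drug, d_mask), self.protein_cnn(h_prot, p_mask)

    def public_early(
        self, h_drug: Tensor, d_mask: np.ndarray, h_prot: Tensor, p_mask: np.ndarray
    ) -> tuple[Tensor, Tensor]:
        z_dp = self.mhca_dp(h_drug, h_prot, p_mask)
        z_pd = self.mhca_pd(h_prot, h_drug, d_mask)
        return (
            masked_global_max_pool(z_dp, d_mask),
            masked_global_max_pool(z_pd, p_mask),
        )

    def __call__(
        self, h_drug: Tensor, d_mask: np.ndarray, h_prot: Tensor, p_mask: np.ndarray
    ) -> dict[str, Tensor]:
        private_d, private_p = self.private_instances(h_drug, d_mask, h_prot, p_mask)
        public_dp, public_pd = self.public_early(h_drug, d_mask, h_prot, p_mask)
        return {
            "public_dp": public_dp,
            "public_pd": public_pd,
            "public_concat": concat([private_d, private_p], axis=-1),
            "private_d": private_d,
        }

    def build_instance_set(
        self,
        h_drug: np.ndarray,
        d_mask: np.ndarray,
        h_prot: np.ndarray,
        p_mask: np.ndarray,
    ) -> InstanceSet:
        """Single-pair convenience wrapper returning plain arrays."""
        out = self(
            Tensor(np.asarray(h_drug)[None]),
            np.asarray(d_mask, bool)[None],
            Tensor(np.asarray(h_prot)[None]),
            np.asarray(p_mask, bool)[None],
        )
        return InstanceSet(
            public_dp=out["public_dp"].data[0],
            public_pd=out["public_pd"].data[0],
            public_concat=out["public_concat"].data[0],
            private_d=out["private_d"].data[0],
        )
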