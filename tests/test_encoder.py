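"""Transformer encoder against straight-line scalar reference computations.

The oracles below re-derive attention, the feed-forward block and the
post-norm layer composition with explicit loops and no batching, sharing no
code with the implementation.
"""

import numpy as np
import pytest

from mildta._autodiff import Tensor
from mildta.encoder import (
    EncoderConfig,
    EncoderLayer,
    MultiHeadAttention,
    TransformerEncoder,
    attention,
    encode_pair,
    positional_encoding,
    self_attention_head,
)


# ---------------------------------------------------------------- oracles
def oracle_softmax(v):
    e = np.exp(v - v.max())
    return e / e.sum()


def oracle_attention(q, k, v, mask, scale):
    """Row-by-row softmax attention with explicit loops."""
    T_q, T_k = q.shape[0], k.shape[0]
    out = np.zeros((T_q, v.shape[1]))
    for t in range(T_q):
        scores = np.array([q[t] @ k[s] * scale for s in range(T_k)])
        if mask is not None:
            scores = np.where(mask, scores, -np.inf)
        w = oracle_softmax(scores)
        out[t] = sum(w[s] * v[s] for s in range(T_k))
    return out


def oracle_layernorm(x, gain, shift, eps=1e-5):
    out = np.zeros_like(x)
    for t in range(x.shape[0]):
        mu = x[t].mean()
        var = ((x[t] - mu) ** 2).mean()
        out[t] = (x[t] - mu) / np.sqrt(var + eps) * gain + shift
    return out


def oracle_multihead(x_q, x_kv, mha, kv_mask):
    """Eq-by-eq multi-head attention using the module's weight matrices."""
    wq, wk, wv = mha.wq.weight.data, mha.wk.weight.data, mha.wv.weight.data
    wo = mha.wo.weight.data
    h, dh = mha.n_heads, mha.head_dim
    q_all, k_all, v_all = x_q @ wq, x_kv @ wk, x_kv @ wv
    heads = []
    for j in range(h):
        sl = slice(j * dh, (j + 1) * dh)
        heads.append(
            oracle_attention(q_all[:, sl], k_all[:, sl], v_all[:, sl], kv_mask, 1 / np.sqrt(dh))
        )
    return np.concatenate(heads, axis=1) @ wo


def oracle_encoder_layer(x, layer, mask):
    a = oracle_multihead(x, x, layer.attn, mask)
    h = oracle_layernorm(x + a, layer.norm1.gain.data, layer.norm1.shift.data)
    ffn = (
        np.maximum(h @ layer.ffn1.weight.data + layer.ffn1.bias.data, 0.0)
        @ layer.ffn2.weight.data
        + layer.ffn2.bias.data
    )
    return oracle_layernorm(h + ffn, layer.norm2.gain.data, layer.norm2.shift.data)


# ---------------------------------------------------------------- tests
class TestPositionalEncoding:
    def test_row_zero_alternates_zero_one(self):
        pe = positional_encoding(5, 8)
        np.testing.assert_allclose(pe[0, 0::2], 0.0)
        np.testing.assert_allclose(pe[0, 1::2], 1.0)

    def test_entry_one_zero_is_sin_one(self):
        assert positional_encoding(4, 128)[1, 0] == pytest.approx(np.sin(1.0))
        assert positional_encoding(4, 128)[1, 0] == pytest.approx(0.841471, abs=1e-6)

    def test_values_bounded_by_one(self):
        pe = positional_encoding(64, 32)
        assert np.abs(pe).max() <= 1.0

    def test_closed_form_everywhere(self):
        T, d = 7, 10
        pe = positional_encoding(T, d)
        for p in range(T):
            for i in range(d // 2):
                angle = p / 10000 ** (2 * i / d)
                assert pe[p, 2 * i] == pytest.approx(np.sin(angle))
                assert pe[p, 2 * i + 1] == pytest.approx(np.cos(angle))

    def test_odd_dim_rejected(self):
        with pytest.raises(ValueError):
            positional_encoding(4, 7)


class TestSelfAttentionHead:
    def test_singleton_sequence_returns_value_row(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(1, 3))
        ws = tuple(rng.normal(size=(3, 3)) for _ in range(3))
        out = self_attention_head(x, ws)
        np.testing.assert_allclose(out, x @ ws[2], atol=1e-12)

    def test_hand_sized_case_matches_oracle(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(2, 2))
        ws = tuple(rng.normal(size=(2, 2)) for _ in range(3))
        out = self_attention_head(x, ws)
        expected = oracle_attention(x @ ws[0], x @ ws[1], x @ ws[2], None, 1 / np.sqrt(2))
        np.testing.assert_allclose(out, expected, atol=1e-10)

    def test_attention_rows_sum_to_one_over_unmasked(self):
        rng = np.random.default_rng(2)
        q = Tensor(rng.normal(size=(4, 3)))
        k = Tensor(rng.normal(size=(4, 3)))
        mask = np.array([True, True, False, True])
        # recover the weights by attending over one-hot values
        w = attention(q, k, Tensor(np.eye(4)), mask, 1 / np.sqrt(3)).data
        np.testing.assert_allclose(w.sum(axis=1), 1.0, atol=1e-12)
        np.testing.assert_allclose(w[:, 2], 0.0, atol=1e-12)

    def test_all_masked_rejected(self):
        x = np.ones((3, 2))
        ws = tuple(np.eye(2) for _ in range(3))
        with pytest.raises(ValueError):
            self_attention_head(x, ws, mask=np.zeros(3, bool))


class TestEncoderLayer:
    @pytest.fixture()
    def layer(self):
        cfg = EncoderConfig(n_layers=1, n_heads=2, d_model=4, ffn_dim=8)
        return EncoderLayer(cfg, np.random.default_rng(5))

    def test_output_shape_matches_input(self, layer):
        x = np.random.default_rng(0).normal(size=(1, 3, 4))
        out = layer(Tensor(x), np.ones((1, 3), bool))
        assert out.shape == x.shape

    def test_zero_ffn_reduces_to_layernorm(self, layer):
        layer.ffn2.weight.data[:] = 0.0
        layer.ffn2.bias.data[:] = 0.0
        rng = np.random.default_rng(3)
        x = rng.normal(size=(1, 3, 4))
        out = layer(Tensor(x), np.ones((1, 3), bool)).data[0]
        a = oracle_multihead(x[0], x[0], layer.attn, np.ones(3, bool))
        h = oracle_layernorm(x[0] + a, layer.norm1.gain.data, layer.norm1.shift.data)
        np.testing.assert_allclose(out, oracle_layernorm(h, layer.norm2.gain.data,
                                                         layer.norm2.shift.data), atol=1e-10)

    def test_matches_scalar_oracle(self, layer):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(3, 4))
        mask = np.array([True, True, False])
        out = layer(Tensor(x[None]), mask[None]).data[0]
        expected = oracle_encoder_layer(x, layer, mask)
        np.testing.assert_allclose(out[:2], expected[:2], atol=1e-5)

    def test_non_finite_input_rejected(self, layer):
        x = np.full((1, 3, 4), np.nan)
        with pytest.raises(ValueError):
            layer(Tensor(x), np.ones((1, 3), bool))

    def test_layernorm_rows_are_standardized(self, layer):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(1, 5, 4))
        out = layer(Tensor(x), np.ones((1, 5), bool)).data[0]
        # unit gain / zero shift at init, so each row is standardized
        np.testing.assert_allclose(out.mean(axis=1), 0.0, atol=1e-8)
        np.testing.assert_allclose(out.var(axis=1), 1.0, atol=1e-3)


class TestTransformerEncoder:
    def _make(self, n_layers, rng_seed=0, max_len=6, n_ids=11, d_model=4):
        cfg = EncoderConfig(n_layers=n_layers, n_heads=2, d_model=d_model, ffn_dim=8)
        return TransformerEncoder(
            n_ids, max_len, cfg, np.random.default_rng(rng_seed)
        )

    def test_zero_layers_is_embedding_plus_position(self):
        enc = self._make(0)
        ids = np.array([[2, 5, 3]])
        mask = np.ones((1, 3), bool)
        out = enc(ids, mask).data[0]
        expected = enc.embed.weight.data[ids[0]] + enc.pos[:3]
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_out_of_range_ids_rejected(self):
        enc = self._make(1)
        with pytest.raises(ValueError, match="out of range"):
            enc(np.array([[2, 99]]), np.ones((1, 2), bool))

    def test_pad_content_cannot_leak_into_unmasked_rows(self):
        enc = self._make(2, rng_seed=7)
        ids = np.array([[2, 5, 3, 0, 0, 0]])
        mask = np.array([[True, True, True, False, False, False]])
        base = enc(ids, mask).data[0]
        ids2 = ids.copy()
        ids2[0, 3:] = [7, 9, 4]  # mutate pad tail content
        out2 = enc(ids2, mask).data[0]
        np.testing.assert_allclose(base[:3], out2[:3], atol=1e-12)

    def test_two_stacks_share_nothing(self):
        rng = np.random.default_rng(0)
        drug_enc = self._make(1, rng_seed=1)
        prot_enc = self._make(1, rng_seed=2)
        d_names = set(drug_enc.parameters())
        ids = np.array([2, 3, 4, 0, 0, 0])
        mask = np.array([True, True, True, False, False, False])
        (hd, md), (hp, mp) = encode_pair((ids, mask), (ids, mask), drug_enc, prot_enc)
        assert hd.shape == hp.shape == (6, 4)
        assert not np.allclose(hd, hp)  # independent parameters

    def test_full_stack_matches_layerwise_oracle(self):
        enc = self._make(2, rng_seed=9)
        ids = np.array([[2, 7, 4]])
        mask = np.ones((1, 3), bool)
        out = enc(ids, mask).data[0]
        h = enc.embed.weight.data[ids[0]] + enc.pos[:3]
        for layer in enc.layers:
            h = oracle_encoder_layer(h, layer, mask[0])
        np.testing.assert_allclose(out, h, atol=1e-5)
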