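"""Instance generators: dilated conv, gate blocks, MHCA, pooling, bags."""

import numpy as np
import pytest

from mildta._autodiff import Tensor
from mildta.encoder import EncoderConfig
from mildta.instances import (
    CrossAttentionBlock,
    DilatedConv1d,
    GateBlock,
    GatedCnn,
    GatedCnnConfig,
    InstanceGenerator,
    dilated_conv_1d,
    masked_global_max_pool,
)
from test_encoder import oracle_layernorm, oracle_multihead


# ---------------------------------------------------------------- oracles
def oracle_dilated_conv(x, f, d):
    """Literal evaluation of out[s] = sum_i f(i) * x[s - d*i]."""
    out = np.zeros(len(x))
    for s in range(len(x)):
        for i in range(len(f)):
            j = s - d * i
            if j >= 0:
                out[s] += f[i] * x[j]
    return out


def oracle_gate_block(x, block):
    """Straight-line conv -> split -> gate -> LayerNorm -> residual."""
    T, C = x.shape
    w, b = block.conv.weight.data, block.conv.bias.data
    k, d = block.conv.kernel_size, block.conv.dilation
    conv = np.zeros((T, 2 * C))
    for t in range(T):
        for co in range(2 * C):
            acc = b[co]
            for i in range(k):
                j = t - d * i
                if j >= 0:
                    acc += x[j] @ w[i, :, co]
            conv[t, co] = acc
    h_l, h_r = conv[:, :C], conv[:, C:]
    gated = h_l * (1.0 / (1.0 + np.exp(-h_r)))
    return oracle_layernorm(gated, block.norm.gain.data, block.norm.shift.data) + x


# ---------------------------------------------------------------- tests
class TestDilatedConv1d:
    def test_kernel_one_is_identity(self):
        x = [3.0, -1.0, 2.0]
        np.testing.assert_allclose(dilated_conv_1d(x, [1.0], d=1), x)

    def test_printed_example_position_four(self):
        out = dilated_conv_1d([1, 2, 3, 4, 5], [1, 1, 1], d=2)
        assert out[4] == 9.0  # x4 + x2 + x0 = 5 + 3 + 1

    def test_zero_input_gives_zero_output(self):
        np.testing.assert_allclose(
            dilated_conv_1d(np.zeros(7), [0.3, -1.2, 2.0], d=3), 0.0
        )

    @pytest.mark.parametrize("d", [1, 2, 3])
    def test_matches_literal_sum_oracle(self, d):
        rng = np.random.default_rng(d)
        x, f = rng.normal(size=10), rng.normal(size=3)
        np.testing.assert_allclose(
            dilated_conv_1d(x, f, d), oracle_dilated_conv(x, f, d), atol=1e-12
        )

    def test_module_matches_functional_per_channel(self):
        rng = np.random.default_rng(0)
        conv = DilatedConv1d(1, 1, kernel_size=3, dilation=2, rng=rng)
        conv.bias.data[:] = 0.0
        x = rng.normal(size=6)
        out = conv(Tensor(x[None, :, None])).data[0, :, 0]
        np.testing.assert_allclose(
            out, dilated_conv_1d(x, conv.weight.data[:, 0, 0], 2), atol=1e-12
        )


class TestGateBlock:
    @pytest.fixture()
    def block(self):
        return GateBlock(2, kernel_size=2, dilation=1, rng=np.random.default_rng(3))

    def test_zero_gate_passes_half_content(self, block):
        # zero the gate-half conv output: sigma(0) = 0.5 scales the content
        block.conv.weight.data[:, :, 2:] = 0.0
        block.conv.bias.data[:] = 0.0
        rng = np.random.default_rng(1)
        x = rng.normal(size=(4, 2))
        h = block.conv(Tensor(x[None])).data[0]
        out = block(Tensor(x[None])).data[0]
        expected = oracle_layernorm(
            0.5 * h[:, :2], block.norm.gain.data, block.norm.shift.data
        ) + x
        np.testing.assert_allclose(out, expected, atol=1e-10)

    def test_saturated_gate_passes_full_content(self, block):
        block.conv.bias.data[2:] = 50.0  # sigma(+large) ~ 1
        rng = np.random.default_rng(2)
        x = rng.normal(size=(4, 2))
        h = block.conv(Tensor(x[None])).data[0]
        out = block(Tensor(x[None])).data[0]
        expected = oracle_layernorm(
            h[:, :2] * 1.0, block.norm.gain.data, block.norm.shift.data
        ) + x
        np.testing.assert_allclose(out, expected, atol=1e-6)

    def test_matches_scalar_oracle(self, block):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(4, 2))
        out = block(Tensor(x[None])).data[0]
        np.testing.assert_allclose(out, oracle_gate_block(x, block), atol=1e-5)


class TestGlobalMaxPool:
    def test_constant_map_pools_to_constant(self):
        x = np.full((1, 3, 4), 2.5)
        out = masked_global_max_pool(Tensor(x), np.ones((1, 3), bool))
        np.testing.assert_allclose(out.data, 2.5)

    def test_matches_enumerated_max(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(2, 3, 5))
        mask = np.array([[True, True, True], [True, False, True]])
        out = masked_global_max_pool(Tensor(x), mask).data
        for b in range(2):
            for c in range(5):
                vals = [x[b, t, c] for t in range(3) if mask[b, t]]
                assert out[b, c] == max(vals)

    def test_all_masked_rejected(self):
        with pytest.raises(ValueError):
            masked_global_max_pool(Tensor(np.ones((1, 3, 2))), np.zeros((1, 3), bool))


class TestCrossAttention:
    def _cfg(self, d=4, h=2):
        return EncoderConfig(n_layers=1, n_heads=h, d_model=d, ffn_dim=8)

    def test_singleton_kv_broadcasts_value_transform(self):
        mhca = CrossAttentionBlock(self._cfg(), np.random.default_rng(0))
        rng = np.random.default_rng(1)
        x1 = rng.normal(size=(3, 4))
        x2 = rng.normal(size=(1, 4))
        out = mhca(Tensor(x1[None]), Tensor(x2[None]), np.ones((1, 1), bool)).data[0]
        # with one key, every attention weight is 1: MultiHead reduces to
        # the value transform of the single row, added to each query row
        v_row = (x2 @ mhca.mha.wv.weight.data) @ mhca.mha.wo.weight.data
        np.testing.assert_allclose(out, x1 + v_row, atol=1e-10)

    def test_toy_case_matches_eq_oracle(self):
        mhca = CrossAttentionBlock(self._cfg(), np.random.default_rng(2))
        rng = np.random.default_rng(3)
        x1, x2 = rng.normal(size=(2, 4)), rng.normal(size=(3, 4))
        mask2 = np.array([True, False, True])
        out = mhca(Tensor(x1[None]), Tensor(x2[None]), mask2[None]).data[0]
        expected = x1 + oracle_multihead(x1, x2, mhca.mha, mask2)
        np.testing.assert_allclose(out, expected, atol=1e-5)

    def test_all_masked_kv_rejected(self):
        mhca = CrossAttentionBlock(self._cfg(), np.random.default_rng(4))
        with pytest.raises(ValueError):
            mhca(
                Tensor(np.ones((1, 2, 4))),
                Tensor(np.ones((1, 3, 4))),
                np.zeros((1, 3), bool),
            )


class TestInstanceGenerator:
    @pytest.fixture()
    def gen(self):
        enc = EncoderConfig(n_layers=1, n_heads=2, d_model=4, ffn_dim=8)
        cnn = GatedCnnConfig(n_blocks=2, kernel_size=3, n_filters=4, dilation_rates=(1, 2))
        return InstanceGenerator(enc, cnn, np.random.default_rng(0))

    def _inputs(self, seed=1, Td=5, Tp=7, d=4):
        rng = np.random.default_rng(seed)
        h_d, h_p = rng.normal(size=(Td, d)), rng.normal(size=(Tp, d))
        d_mask = np.array([True] * 3 + [False] * (Td - 3))
        p_mask = np.array([True] * 5 + [False] * (Tp - 5))
        return h_d, d_mask, h_p, p_mask

    def test_bag_has_four_instances_with_consistent_widths(self, gen):
        iset = gen.build_instance_set(*self._inputs())
        assert len(iset) == 4
        assert iset.private_d.shape == (4,)
        assert iset.public_dp.shape == iset.public_pd.shape == (4,)
        assert iset.public_concat.shape == (8,)

    def test_concat_halves_are_the_private_features(self, gen):
        h_d, d_mask, h_p, p_mask = self._inputs()
        iset = gen.build_instance_set(h_d, d_mask, h_p, p_mask)
        priv_d, priv_p = gen.private_instances(
            Tensor(h_d[None]), d_mask[None], Tensor(h_p[None]), p_mask[None]
        )
        np.testing.assert_allclose(iset.public_concat[:4], priv_d.data[0])
        np.testing.assert_allclose(iset.public_concat[4:], priv_p.data[0])
        np.testing.assert_allclose(iset.public_concat[:4], iset.private_d)

    def test_pad_positions_cannot_change_any_instance(self, gen):
        h_d, d_mask, h_p, p_mask = self._inputs()
        base = gen.build_instance_set(h_d, d_mask, h_p, p_mask)
        rng = np.random.default_rng(99)
        h_d2, h_p2 = h_d.copy(), h_p.copy()
        h_d2[~d_mask] = rng.normal(size=(np.sum(~d_mask), 4)) * 10
        h_p2[~p_mask] = rng.normal(size=(np.sum(~p_mask), 4)) * 10
        other = gen.build_instance_set(h_d2, d_mask, h_p2, p_mask)
        for a, b in zip(base.as_list(), other.as_list()):
            np.testing.assert_allclose(a, b, atol=1e-12)

    def test_receptive_field_is_bounded_by_dilation_sum(self):
        # k=3 with dilations (1,2,4): position s sees at most 2*(1+2+4)=14 back
        cnn = GatedCnnConfig(n_blocks=3, kernel_size=3, n_filters=4,
                             dilation_rates=(1, 2, 4))
        stack = GatedCnn(cnn, 4, np.random.default_rng(0))
        rng = np.random.default_rng(1)
        T = 20
        x = rng.normal(size=(1, T, 4))
        base = stack.features(Tensor(x)).data[0]
        probe = 16
        x_far = x.copy()
        x_far[0, probe - 15] += 5.0  # beyond the receptive field of `probe`
        far = stack.features(Tensor(x_far)).data[0]
        np.testing.assert_allclose(far[probe], base[probe], atol=1e-12)
        x_near = x.copy()
        x_near[0, probe - 14] += 5.0  # inside the receptive field
        near = stack.features(Tensor(x_near)).data[0]
        assert not np.allclose(near[probe], base[probe])

    def test_causality_no_forward_leakage(self):
        cnn = GatedCnnConfig(n_blocks=2, kernel_size=3, n_filters=4,
                             dilation_rates=(1, 2))
        stack = GatedCnn(cnn, 4, np.random.default_rng(2))
        rng = np.random.default_rng(3)
        x = rng.normal(size=(1, 8, 4))
        base = stack.features(Tensor(x)).data[0]
        x2 = x.copy()
        x2[0, 5:] += 1.0  # later positions only
        out2 = stack.features(Tensor(x2)).data[0]
        np.testing.assert_allclose(out2[:5], base[:5], atol=1e-12)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            GatedCnnConfig(n_blocks=2, dilation_rates=(1,))
        with pytest.raises(ValueError):
            GatedCnnConfig(dilation_rates=(1, 0, 4))
        with pytest.raises(ValueError, match="n_filters"):
            GatedCnn(GatedCnnConfig(), d_model=64, rng=np.random.default_rng(0))
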