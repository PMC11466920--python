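"""Bottleneck dual-attention tests: oracles, identities, and complexity formulas."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from duoseg import DualAttentionConfig, flops_gca, flops_gsa, flops_wmsa
from duoseg.bottleneck import (
    Bottleneck,
    DualAttentionBlock,
    GlobalChannelAttention,
    GlobalSpatialAttention,
)
from duoseg.errors import ShapeError
from duoseg.nn import Tensor, count_matmul_flops

from oracles import channel_attention, dense_cross_attention


def _qkv_weights(mod):
    return (
        mod.q.weight.data, mod.q.bias.data,
        mod.k.weight.data, mod.k.bias.data,
        mod.v.weight.data, mod.v.bias.data,
    )


class TestGlobalSpatialAttention:
    def test_matches_dense_oracle(self, rng):
        gsa = GlobalSpatialAttention(dim=8, heads=1)
        x = rng.normal(size=(1, 9, 8))
        out = gsa(Tensor(x)).data
        attended = dense_cross_attention(x, x, *_qkv_weights(gsa), heads=1)
        expected = attended @ gsa.proj.weight.data.T + gsa.proj.bias.data
        np.testing.assert_allclose(out, expected, rtol=1e-5, atol=1e-10)

    def test_single_token_attention_weight_is_one(self, rng):
        gsa = GlobalSpatialAttention(dim=4, heads=2)
        x = rng.normal(size=(1, 1, 4))
        out = gsa(Tensor(x)).data
        np.testing.assert_allclose(gsa.last_attn, 1.0)
        v = x @ gsa.v.weight.data.T + gsa.v.bias.data
        expected = v @ gsa.proj.weight.data.T + gsa.proj.bias.data
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_identical_tokens_identical_outputs(self, rng):
        gsa = GlobalSpatialAttention(dim=6, heads=3)
        token = rng.normal(size=(1, 1, 6))
        x = np.tile(token, (1, 5, 1))
        out = gsa(Tensor(x)).data
        np.testing.assert_allclose(out, np.broadcast_to(out[:, :1], out.shape), atol=1e-12)

    def test_rows_sum_to_one(self, rng):
        gsa = GlobalSpatialAttention(dim=8, heads=2)
        gsa(Tensor(rng.normal(size=(2, 12, 8))))
        np.testing.assert_allclose(gsa.last_attn.sum(axis=-1), 1.0, atol=1e-6)


class TestGlobalChannelAttention:
    def test_matches_small_matrix_oracle(self, rng):
        gca = GlobalChannelAttention(dim=4)
        x = rng.normal(size=(1, 9, 4))
        out = gca(Tensor(x)).data
        expected = channel_attention(
            x,
            gca.q.weight.data, gca.q.bias.data,
            gca.k.weight.data, gca.k.bias.data,
            gca.v.weight.data, gca.v.bias.data,
            gca.proj.weight.data, gca.proj.bias.data,
            scale=4**-0.5,
        )
        np.testing.assert_allclose(out, expected, rtol=1e-5, atol=1e-10)

    def test_single_channel_weight_is_one(self, rng):
        gca = GlobalChannelAttention(dim=1)
        gca(Tensor(rng.normal(size=(1, 6, 1))))
        np.testing.assert_allclose(gca.last_attn, 1.0)

    def test_token_order_equivariance(self, rng):
        """Channel mixing is computed from token statistics, so permuting the
        tokens permutes the output identically."""
        gca = GlobalChannelAttention(dim=5)
        x = rng.normal(size=(1, 8, 5))
        perm = rng.permutation(8)
        out = gca(Tensor(x)).data
        out_perm = gca(Tensor(x[:, perm])).data
        np.testing.assert_allclose(out_perm, out[:, perm], rtol=1e-8, atol=1e-10)

    def test_channel_rows_sum_to_one(self, rng):
        gca = GlobalChannelAttention(dim=7)
        gca(Tensor(rng.normal(size=(2, 10, 7))))
        assert gca.last_attn.shape[-2:] == (7, 7)
        np.testing.assert_allclose(gca.last_attn.sum(axis=-1), 1.0, atol=1e-6)

    def test_linear_scale_option(self, rng):
        gca = GlobalChannelAttention(dim=4, scale="linear")
        x = rng.normal(size=(1, 6, 4))
        out = gca(Tensor(x)).data
        expected = channel_attention(
            x,
            gca.q.weight.data, gca.q.bias.data,
            gca.k.weight.data, gca.k.bias.data,
            gca.v.weight.data, gca.v.bias.data,
            gca.proj.weight.data, gca.proj.bias.data,
            scale=1.0 / 4,
        )
        np.testing.assert_allclose(out, expected, rtol=1e-5, atol=1e-10)


class TestDualAttentionBlock:
    def _cfg(self, **kw):
        base = dict(embed_dim=8, num_blocks=1, heads=2, mlp_ratio=2.0)
        base.update(kw)
        return DualAttentionConfig(**base)

    def test_zeroed_block_is_identity(self, rng):
        block = DualAttentionBlock(self._cfg())
        for p in block.parameters():
            p.data[...] = 0.0
        x = rng.normal(size=(2, 6, 8))
        np.testing.assert_array_equal(block(Tensor(x)).data, x)

    def test_stacking_equals_repeated_application(self, rng):
        cfg = self._cfg(num_blocks=2)
        bott = Bottleneck(8, cfg)
        x = [Tensor(rng.normal(size=(1, 8, 3, 3)))]
        tokens = bott.embed_tokens(x)
        manual = bott.blocks[1](bott.blocks[0](tokens))
        full = bott(x)
        np.testing.assert_allclose(full.data.reshape(1, 8, 9), manual.data.swapaxes(1, 2), atol=1e-12)

    def test_block_order_configurable(self, rng):
        x = rng.normal(size=(1, 4, 8))
        a = DualAttentionBlock(self._cfg(block_order="GSA_then_GCA"))
        b = DualAttentionBlock(self._cfg(block_order="GCA_then_GSA"))
        # same weights, different order => generally different outputs
        b.load_state_dict(a.state_dict())
        assert not np.allclose(a(Tensor(x)).data, b(Tensor(x)).data)


class TestBottleneckEmbed:
    def test_contract_and_channel_arithmetic(self, rng):
        cfg = DualAttentionConfig(embed_dim=512, num_blocks=1, heads=16)
        bott = Bottleneck(3 * 512, cfg)
        maps = [Tensor(rng.normal(size=(2, 512, 4, 4))) for _ in range(3)]
        tokens = bott.embed_tokens(maps)
        assert tokens.shape == (2, 16, 512)
        assert bott.embed.weight.shape == (512, 1536)  # 3*512 concatenated channels

    def test_extent_mismatch_raises(self, rng):
        bott = Bottleneck(16, DualAttentionConfig(embed_dim=8, num_blocks=1, heads=2))
        maps = [Tensor(rng.normal(size=(1, 8, 4, 4))), Tensor(rng.normal(size=(1, 8, 2, 2)))]
        with pytest.raises(ShapeError, match="extent"):
            bott.embed_tokens(maps)

    def test_zero_inputs_give_bias_determined_tokens(self):
        bott = Bottleneck(8, DualAttentionConfig(embed_dim=8, num_blocks=1, heads=2))
        tokens = bott.embed_tokens([Tensor(np.zeros((1, 8, 2, 2)))]).data
        np.testing.assert_allclose(tokens, np.broadcast_to(tokens[:, :1, :], tokens.shape), atol=1e-12)

    def test_gradient_reaches_all_inputs(self, rng):
        bott = Bottleneck(24, DualAttentionConfig(embed_dim=8, num_blocks=1, heads=2))
        maps = [Tensor(rng.normal(size=(1, 8, 3, 3)), requires_grad=True) for _ in range(3)]
        out = bott(maps)
        (out * out).sum().backward()
        for m in maps:
            assert m.grad is not None and np.any(m.grad)


class TestComplexityFormulas:
    def test_hand_evaluations(self):
        assert flops_wmsa(8, 8, 16, 4) == 98_304
        assert flops_gsa(4, 4, 8) == 8_192
        assert flops_gca(4, 4, 8) == 8_192 - 2 * 4 * 4 * 64

    @given(
        h=st.integers(1, 16), w=st.integers(1, 16), c=st.integers(1, 64), m=st.integers(1, 8)
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_gca_cheaper_than_gsa_by_2hwc2(self, h, w, c, m):
        assert flops_gsa(h, w, c) - flops_gca(h, w, c) == 2 * h * w * c**2
        assert flops_gca(h, w, c) < flops_gsa(h, w, c)
        assert flops_wmsa(h, w, c, m) > 0

    def test_domain_errors(self):
        with pytest.raises(ValueError, match="positive"):
            flops_gsa(0, 4, 8)
        with pytest.raises(ValueError, match="positive"):
            flops_wmsa(4, 4, -1, 2)

    @pytest.mark.parametrize("h,w,c", [(3, 3, 8), (4, 4, 6), (2, 5, 4)])
    def test_instrumented_gsa_matmul_count_matches_formula(self, rng, h, w, c):
        """Counting one multiplication per scalar-product term, a single-head
        forward performs exactly 4hwC^2 + 2(hw)^2 C of them: four C->C
        projections plus the two attention matrix products."""
        gsa = GlobalSpatialAttention(dim=c, heads=1)
        x = Tensor(rng.normal(size=(1, h * w, c)))
        with count_matmul_flops() as counter:
            gsa(x)
        assert counter.flops == flops_gsa(h, w, c)
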