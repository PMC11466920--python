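"""Encoder-branch tests: patch embedding, window attention vs dense oracles,
residual identities, CNN stages, and the dual-encoder contract."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from duoseg import EncoderConfig, nn
from duoseg.encoders import (
    DualEncoder,
    PatchEmbed,
    ConvDownsample,
    ResidualConvBlock,
    SwinBlockPair,
    WindowAttention,
    map_to_tokens,
    tokens_to_map,
    window_partition,
    window_reverse,
)
from duoseg.errors import ShapeError
from duoseg.nn import Tensor

from oracles import dense_mha, shifted_window_attention


def tiny_encoder_cfg():
    return EncoderConfig(
        base_width=8,
        cnn_channels=(8, 16, 32, 64, 128),
        swin_dims=(32, 64, 128),
        num_heads=(4, 8, 16),
        window_size=4,
    )


def zero_parameters(module: nn.Module) -> None:
    for p in module.parameters():
        p.data[...] = 0.0


# ------------------------------------------------------------ patch embedding
class TestPatchEmbed:
    @pytest.mark.parametrize("size,expect", [(64, 16), (256, 64)])
    def test_quarter_resolution(self, rng, size, expect):
        pe = PatchEmbed(dim=32)
        out = pe(Tensor(rng.uniform(0, 1, (1, 1, size, size))))
        assert out.shape == (1, 32, expect, expect)

    def test_rejects_bad_shapes(self, rng):
        pe = PatchEmbed(dim=32)
        with pytest.raises(ShapeError, match="square"):
            pe(Tensor(rng.uniform(0, 1, (1, 1, 64, 32))))
        with pytest.raises(ShapeError, match="divisible"):
            pe(Tensor(rng.uniform(0, 1, (1, 1, 30, 30))))

    def test_batch_independence(self, rng):
        pe = PatchEmbed(dim=16)
        img = rng.uniform(0, 1, (1, 1, 32, 32))
        batch = Tensor(np.concatenate([img, img], axis=0))
        out = pe(batch).data
        np.testing.assert_array_equal(out[0], out[1])


# ------------------------------------------------------------------- windows
class TestWindowPartition:
    @pytest.mark.parametrize("window,n_windows,tokens", [(2, 4, 4), (4, 1, 16)])
    def test_window_counts(self, rng, window, n_windows, tokens):
        x = Tensor(rng.normal(size=(1, 3, 4, 4)))
        win = window_partition(x, window)
        assert win.shape == (n_windows, tokens, 3)

    @given(
        b=st.integers(1, 2),
        c=st.integers(1, 4),
        hw=st.sampled_from([4, 8]),
        window=st.sampled_from([2, 4]),
    )
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_roundtrip_is_exact_inverse(self, b, c, hw, window):
        data = np.random.default_rng(b * 100 + c).normal(size=(b, c, hw, hw))
        x = Tensor(data)
        back = window_reverse(window_partition(x, window), window, (hw, hw))
        np.testing.assert_array_equal(back.data, data)

    def test_indivisible_extent_raises(self, rng):
        with pytest.raises(ShapeError, match="divisible"):
            window_partition(Tensor(rng.normal(size=(1, 2, 6, 6))), 4)

    def test_token_map_roundtrip(self, rng):
        data = rng.normal(size=(2, 5, 4, 6))
        x = Tensor(data)
        np.testing.assert_array_equal(tokens_to_map(map_to_tokens(x), (4, 6)).data, data)


# ----------------------------------------------------------- window attention
class TestWindowAttentionOracles:
    def test_full_window_equals_dense_attention(self, rng):
        """Window covering the whole grid = dense global softmax attention."""
        dim, heads, m = 16, 4, 4
        attn = WindowAttention(dim, heads, m, rel_pos_bias=False)
        x = rng.normal(size=(2, m * m, dim))
        out = attn(Tensor(x)).data
        expected = dense_mha(
            x,
            attn.qkv.weight.data,
            attn.qkv.bias.data,
            attn.proj.weight.data,
            attn.proj.bias.data,
            heads,
        )
        np.testing.assert_allclose(out, expected, rtol=1e-5, atol=1e-10)

    def test_attention_rows_sum_to_one(self, rng):
        attn = WindowAttention(8, 2, 2, rel_pos_bias=True)
        attn(Tensor(rng.normal(size=(6, 4, 8))))
        sums = attn.last_attn.sum(axis=-1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-6)

    def test_shifted_pass_matches_roll_and_mask_oracle(self, rng):
        """SW-MSA on a 4x4 grid, M=2: roll by (-1,-1), mask wraps, roll back."""
        dim, heads, m = 8, 2, 2
        block = SwinBlockPair(dim, heads, m, mlp_ratio=1.0, rel_pos_bias=False)
        grid = (4, 4)
        tokens = rng.normal(size=(1, 16, dim))

        out = block._attend(Tensor(tokens), grid, block.attn_shifted, shift=1).data

        a = block.attn_shifted

        def one_window(win_tokens, mask):
            return dense_mha(
                win_tokens[None],
                a.qkv.weight.data,
                a.qkv.bias.data,
                a.proj.weight.data,
                a.proj.bias.data,
                heads,
                extra_logits=mask,
            )[0]

        expected = shifted_window_attention(
            tokens.reshape(4, 4, dim), one_window, window=m, shift=1
        ).reshape(1, 16, dim)
        np.testing.assert_allclose(out, expected, rtol=1e-5, atol=1e-10)

    def test_zeroed_block_pair_is_identity(self, rng):
        block = SwinBlockPair(16, 4, 2, rel_pos_bias=True)
        zero_parameters(block)
        tokens = rng.normal(size=(2, 16, 16))
        out = block(Tensor(tokens), (4, 4)).data
        np.testing.assert_array_equal(out, tokens)

    def test_relative_position_bias_changes_output(self, rng):
        """The learned positional term must actually enter the logits."""
        attn = WindowAttention(8, 2, 2, rel_pos_bias=True)
        x = Tensor(rng.normal(size=(1, 4, 8)))
        base = attn(x).data.copy()
        attn.bias_table.data += 1.5 * np.arange(attn.bias_table.size).reshape(
            attn.bias_table.shape
        )
        assert not np.allclose(attn(x).data, base)


# ---------------------------------------------------------------- CNN branch
class TestCnnBranch:
    def test_stage1_keeps_resolution(self, rng):
        stage = ResidualConvBlock(1, 8, stride=1)
        out = stage(Tensor(rng.uniform(0, 1, (2, 1, 64, 64))))
        assert out.shape == (2, 8, 64, 64)

    def test_stride2_stage_halves(self, rng):
        stage = ResidualConvBlock(64, 128, stride=2)
        out = stage(Tensor(rng.normal(size=(1, 64, 32, 32))))
        assert out.shape == (1, 128, 16, 16)

    def test_zero_input_gives_bias_determined_constant_map(self):
        stage = ResidualConvBlock(4, 8, stride=1)
        out = stage(Tensor(np.zeros((1, 4, 8, 8)))).data
        # convolution of zeros is spatially constant; BN biases set the level
        assert np.ptp(out.reshape(8, -1), axis=1).max() < 1e-12

    def test_zeroed_main_path_reduces_to_shortcut(self, rng):
        stage = ResidualConvBlock(4, 8, stride=2)
        for name in ("conv1", "conv2", "bn1", "bn2"):
            zero_parameters(getattr(stage, name))
        x = Tensor(rng.normal(size=(1, 4, 8, 8)))
        out = stage(x).data
        short = nn.relu(stage.short_bn(stage.short_conv(x))).data
        np.testing.assert_allclose(out, short, atol=1e-12)

    def test_conv_downsample(self, rng):
        down = ConvDownsample(16, 32)
        assert down(Tensor(rng.normal(size=(2, 16, 16, 16)))).shape == (2, 32, 8, 8)
        twice = down.conv
        assert ConvDownsample(32, 64)(down(Tensor(rng.normal(size=(1, 16, 16, 16))))).shape == (
            1,
            64,
            4,
            4,
        )
        with pytest.raises(ShapeError, match="odd"):
            down(Tensor(rng.normal(size=(1, 16, 5, 5))))

    def test_stage_param_count_closed_form_and_quadrupling(self):
        from oracles import expected_param_count_cnn_stage

        for in_ch, out_ch, stride in [(1, 8, 1), (8, 16, 2), (64, 128, 2)]:
            stage = ResidualConvBlock(in_ch, out_ch, stride)
            assert stage.num_parameters() == expected_param_count_cnn_stage(in_ch, out_ch, stride)
        # doubling widths quadruples the dominant conv terms
        small = ResidualConvBlock(32, 64, 2).num_parameters()
        big = ResidualConvBlock(64, 128, 2).num_parameters()
        assert 3.5 < big / small < 4.1


# --------------------------------------------------------------- dual encoder
class TestDualEncoder:
    def test_stage_extents_and_pairing(self, rng):
        enc = DualEncoder(tiny_encoder_cfg())
        outs = enc(Tensor(rng.uniform(0, 1, (1, 1, 64, 64))))
        cnn_extents = [f.shape[2] for f in outs.cnn_feats]
        swin_extents = [f.shape[2] for f in outs.swin_feats]
        assert cnn_extents == [64, 32, 16, 8, 4]
        assert swin_extents == [16, 8, 4]
        for i in range(3):
            assert outs.swin_feats[i].shape[2:] == outs.cnn_feats[i + 2].shape[2:]

    def test_every_parameter_receives_gradient(self, rng):
        enc = DualEncoder(tiny_encoder_cfg())
        outs = enc(Tensor(rng.uniform(0, 1, (1, 1, 64, 64))))
        loss = sum(
            ((f * f).sum() for f in outs.cnn_feats + outs.swin_feats),
            start=Tensor(0.0),
        )
        loss.backward()
        dead = [n for n, p in enc.named_parameters() if p.grad is None or not np.any(p.grad)]
        assert dead == []

    def test_rejects_invalid_images(self, rng):
        enc = DualEncoder(tiny_encoder_cfg())
        with pytest.raises(ShapeError, match="square"):
            enc(Tensor(rng.uniform(0, 1, (1, 1, 64, 32))))
        with pytest.raises(ShapeError, match="32"):
            enc(Tensor(rng.uniform(0, 1, (1, 1, 48, 48))))

    def test_config_validates_fusable_widths(self):
        with pytest.raises(Exception, match="must equal"):
            EncoderConfig(swin_dims=(64, 256, 512))
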