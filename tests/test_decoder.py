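"""Two-way mask decoder: stage semantics, oracle equivalence, counts."""

import numpy as np
import pytest
from scipy.special import erf

import sonoseg as ss
from sonoseg.decoder import (DecoderConfig, MaskDecoder, TwoWayBlock,
                             decoder_layer, tiny_decoder_config)
from sonoseg.nn import Attention, Identity, Tensor
from sonoseg.prompts import PromptEmbedding


def small_config(**kw):
    base = dict(embed_dim=8, depth=2, num_heads=2, mlp_hidden=16,
                num_mask_tokens=4, seed=3)
    base.update(kw)
    return DecoderConfig(**base)


# ---------------------------------------------------------------------------
# straight-line numpy re-implementation (loops, no package autograd code)

def np_linear(x, layer):
    return x @ layer.weight.data.T + layer.bias.data


def np_ln(x, layer):
    mu = x.mean(-1, keepdims=True)
    var = x.var(-1, keepdims=True)
    return (x - mu) / np.sqrt(var + layer.eps) * layer.weight.data + layer.bias.data


def np_gelu(x):
    return 0.5 * x * (1 + erf(x / np.sqrt(2)))


def np_attention(q, k, v, attn: Attention):
    qs, ks, vs = np_linear(q, attn.q_proj), np_linear(k, attn.k_proj), np_linear(v, attn.v_proj)
    h = attn.num_heads
    dh = attn.internal_dim // h
    out = np.zeros((q.shape[0], attn.internal_dim))
    for head in range(h):
        sl = slice(head * dh, (head + 1) * dh)
        logits = qs[:, sl] @ ks[:, sl].T / np.sqrt(dh)
        e = np.exp(logits - logits.max(axis=1, keepdims=True))
        w = e / e.sum(axis=1, keepdims=True)
        out[:, sl] = w @ vs[:, sl]
    return np_linear(out, attn.out_proj)


def np_block(tokens, src, blk: TwoWayBlock):
    t = np_ln(tokens + np_attention(tokens, tokens, tokens, blk.self_attn), blk.norm1)
    t = np_ln(t + np_attention(t, src, src, blk.cross_attn_token_to_image), blk.norm2)
    mlp = np_linear(np_gelu(np_linear(t, blk.mlp.lin1)), blk.mlp.lin2)
    t = np_ln(t + mlp, blk.norm3)
    src = np_ln(src + np_attention(src, t, t, blk.cross_attn_image_to_token), blk.norm4)
    return t, src


def np_conv_t(x, conv):
    cin, h, w = x.shape
    cout = conv.out_channels
    y = np.zeros((cout, 2 * h, 2 * w))
    W = conv.weight.data
    for i in range(h):
        for j in range(w):
            for c in range(cin):
                y[:, 2 * i:2 * i + 2, 2 * j:2 * j + 2] += x[c, i, j] * W[c]
    return y + conv.bias.data[:, None, None]


def np_ln2d(x, layer):
    y = x.transpose(1, 2, 0)
    mu = y.mean(-1, keepdims=True)
    var = y.var(-1, keepdims=True)
    y = (y - mu) / np.sqrt(var + layer.eps) * layer.weight.data + layer.bias.data
    return y.transpose(2, 0, 1)


def np_decode(decoder: MaskDecoder, feats, prompt):
    cfg = decoder.config
    h, w, E = feats.shape
    src = (feats + prompt.dense).reshape(h * w, E)
    tokens = np.concatenate([decoder.iou_token.data, decoder.mask_tokens.data,
                             prompt.sparse], axis=0)
    for blk in decoder.layers:
        tokens, src = np_block(tokens, src, blk)
    tokens = np_ln(tokens + np_attention(tokens, src, src,
                                         decoder.final_attn_token_to_image),
                   decoder.norm_final_attn)
    grid = src.reshape(h, w, E).transpose(2, 0, 1)
    up = np_gelu(np_ln2d(np_conv_t(grid, decoder.upscale_conv1), decoder.upscale_norm))
    up = np_gelu(np_conv_t(up, decoder.upscale_conv2))
    out = []
    for c in range(cfg.num_classes):
        x = tokens[1 + c]
        mlps = decoder.output_hypernetworks_mlps[c].layers
        for i, lay in enumerate(mlps):
            x = np_linear(x, lay)
            if i < len(mlps) - 1:
                x = np.maximum(x, 0)
        out.append(np.einsum("c,chw->hw", x, up))
    return np.stack(out)


def make_prompt(rng, h, w, E, n_sparse=2):
    return PromptEmbedding(sparse=rng.normal(size=(n_sparse, E)),
                           dense=rng.normal(size=(h, w, E)) * 0.1)


# ---------------------------------------------------------------------------

class TestDecoderLayer:
    def test_shape_preservation(self):
        rng = np.random.default_rng(0)
        blk = TwoWayBlock(DecoderConfig(seed=1), np.random.default_rng(1))
        tokens = Tensor(rng.normal(size=(6, 256)))
        feats = Tensor(rng.normal(size=(256, 256)))
        t, s = decoder_layer(tokens, feats, blk)
        assert t.shape == (6, 256) and s.shape == (256, 256)

    def test_zeroed_weights_reduce_to_identity(self):
        blk = TwoWayBlock(small_config(), np.random.default_rng(0))
        for p in blk.parameters():
            p.data[:] = 0.0
        for name in ("norm1", "norm2", "norm3", "norm4"):
            setattr(blk, name, Identity())
        rng = np.random.default_rng(2)
        tokens = Tensor(rng.normal(size=(5, 8)))
        feats = Tensor(rng.normal(size=(4, 8)))
        t, s = blk(tokens, feats)
        assert np.allclose(t.data, tokens.data)
        assert np.allclose(s.data, feats.data)

    def test_single_vs_multi_head_on_one_token(self):
        rng = np.random.default_rng(7)
        a1 = Attention(8, 1, np.random.default_rng(5))
        a8 = Attention(8, 8, np.random.default_rng(9))
        for src, dst in ((a1, a8),):
            dst.q_proj.load_state_dict(src.q_proj.state_dict())
            dst.k_proj.load_state_dict(src.k_proj.state_dict())
            dst.v_proj.load_state_dict(src.v_proj.state_dict())
            dst.out_proj.load_state_dict(src.out_proj.state_dict())
        x = Tensor(rng.normal(size=(1, 8)))
        # one query, one key: softmax is 1 regardless of head split
        assert np.allclose(a1(x, x, x).data, a8(x, x, x).data, atol=1e-12)

    def test_dimension_mismatch_names_stage(self):
        from sonoseg.errors import ShapeError
        blk = TwoWayBlock(small_config(), np.random.default_rng(0))
        with pytest.raises(ShapeError, match="self-attention"):
            blk(Tensor(np.zeros((3, 8))), Tensor(np.zeros((4, 6))))


class TestDecodeMasks:
    def test_16x16_grid_gives_64x64_logits(self, rng):
        dec = MaskDecoder(DecoderConfig(seed=0))
        prompt = make_prompt(rng, 16, 16, 256)
        _, out = dec.decode_masks(rng.normal(size=(16, 16, 256)), prompt)
        assert out.logits.shape == (2, 64, 64)

    def test_two_class_channels(self, rng):
        dec = MaskDecoder(small_config())
        prompt = make_prompt(rng, 2, 2, 8)
        _, out = dec.decode_masks(rng.normal(size=(2, 2, 8)), prompt)
        assert out.logits.shape[0] == 2
        assert out.class_index == {"needle": 0, "tumor": 1}

    def test_deterministic_forward(self, rng):
        dec = MaskDecoder(small_config())
        feats = rng.normal(size=(2, 2, 8))
        prompt = make_prompt(rng, 2, 2, 8)
        a = dec.decode_masks(feats, prompt)[1].logits
        b = dec.decode_masks(feats, prompt)[1].logits
        assert np.array_equal(a, b)

    def test_matches_straight_line_oracle(self, rng):
        dec = MaskDecoder(small_config())
        feats = rng.normal(size=(2, 2, 8))
        prompt = make_prompt(rng, 2, 2, 8)
        logits, out = dec.decode_masks(feats, prompt)
        oracle = np_decode(dec, feats, prompt)
        assert np.allclose(out.logits, oracle, atol=1e-6)

    def test_batched_decode_matches_single(self, rng):
        dec = MaskDecoder(small_config())
        feats = rng.normal(size=(3, 2, 2, 8))
        prompts = [make_prompt(rng, 2, 2, 8) for _ in range(3)]
        batched = dec.decode_masks_batch(
            Tensor(feats), Tensor(np.stack([p.sparse for p in prompts])),
            Tensor(np.stack([p.dense for p in prompts]))).data
        for i in range(3):
            single = dec.decode_masks(feats[i], prompts[i])[1].logits
            assert np.allclose(batched[i], single, atol=1e-10)

    def test_bidirectional_gradients_nonzero(self, rng):
        dec = MaskDecoder(small_config())
        feats = Tensor(rng.normal(size=(2, 2, 8)), requires_grad=True)
        prompt = make_prompt(rng, 2, 2, 8)
        blk = dec.layers[0]
        tokens = Tensor(rng.normal(size=(5, 8)), requires_grad=True)
        t, s = blk(tokens, feats.reshape(4, 8))
        # weighted probe: a plain sum of a layer-norm output is constant
        wt = Tensor(rng.normal(size=(5, 8)))
        ws = Tensor(rng.normal(size=(4, 8)))
        ((t * wt).sum() + (s * ws).sum()).backward()
        assert np.abs(tokens.grad).max() > 0
        assert np.abs(feats.grad).max() > 0

    def test_corner_token_permutation_symmetry(self, rng):
        # swapping the two prompt corner tokens permutes rows of the token
        # stream but leaves the class-token outputs unchanged
        dec = MaskDecoder(small_config())
        feats = rng.normal(size=(2, 2, 8))
        sparse = rng.normal(size=(2, 8))
        dense = rng.normal(size=(2, 2, 8)) * 0.1
        a = dec.decode_masks(feats, PromptEmbedding(sparse=sparse, dense=dense))[1].logits
        b = dec.decode_masks(feats, PromptEmbedding(sparse=sparse[::-1].copy(),
                                                    dense=dense))[1].logits
        assert np.allclose(a, b, atol=1e-9)


class TestParameterCounts:
    def test_reference_config_rounds_to_4m(self):
        dec = MaskDecoder(DecoderConfig())
        n = dec.trainable_parameters()
        assert round(n / 1e6) == 4
        assert n == 4_058_340      # exact reference decoder count

    def test_tiny_config_under_500k(self):
        dec = MaskDecoder(tiny_decoder_config())
        assert dec.trainable_parameters() < 500_000

    def test_count_monotone_in_mlp_hidden(self):
        a = MaskDecoder(small_config(mlp_hidden=16)).trainable_parameters()
        b = MaskDecoder(small_config(mlp_hidden=32)).trainable_parameters()
        assert b > a

    def test_invalid_configs_rejected(self):
        from sonoseg.errors import ConfigurationError
        with pytest.raises(ConfigurationError):
            DecoderConfig(embed_dim=250, num_heads=8)
        with pytest.raises(ConfigurationError):
            DecoderConfig(upsample_factor=2)
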