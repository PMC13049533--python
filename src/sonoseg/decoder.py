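"""Two-way transformer mask decoder — the only trainable component.

Each layer runs four residual + layer-norm stages:

    T'   = LN(T   + SelfAttn(Q=T,  K=T,  V=T))          token self-attention
    T''  = LN(T'  + CrossAttn(Q=T', K=I,  V=I))         prompt -> image
    T''' = LN(T'' + MLP(T''))                           point-wise FFN (GELU)
    I'   = LN(I   + CrossAttn(Q=I,  K=T''', V=T'''))    image -> prompt

so information flows both ways between the prompt tokens and the image
embedding. After ``depth`` layers (plus a final token-to-image attention),
the image stream is upsampled 4x by two stride-2 transposed convolutions
and each class token is mapped by a small MLP to a mask embedding whose
per-pixel dot product with the upsampled features gives the mask logits.

The token bank mirrors the reference release (one IoU token, four mask
tokens, IoU head) for checkpoint compatibility; class 0/1 decode from mask
tokens 0/1 and the remaining tokens ride along untrained.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .errors import ConfigurationError, ShapeError
from .nn import (Attention, ConvTranspose2x2, LayerNorm, LayerNorm2d, MLP,
                 MLPBlock, Module, Parameter, Tensor, concat, gelu)
from .prompts import PromptEmbedding


@dataclasses.dataclass
class DecoderConfig:
    embed_dim: int = 256
    depth: int = 2
    num_heads: int = 8
    mlp_hidden: int = 2048
    num_classes: int = 2                 # needle, tumor
    num_mask_tokens: int = 4             # reference token bank size
    head_mlp_depth: int = 3
    upsample_factor: int = 4             # fixed: two stride-2 transposed convs
    attention_downsample_rate: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.embed_dim % self.num_heads:
            raise ConfigurationError("embed_dim must be divisible by num_heads")
        if self.upsample_factor != 4:
            raise ConfigurationError("upsample_factor is fixed at 4")
        if self.num_classes > self.num_mask_tokens:
            raise ConfigurationError("need at least one mask token per class")

    @property
    def mask_embed_dim(self) -> int:
        return self.embed_dim // 8


@dataclasses.dataclass
class MaskLogits:
    """Per-class logit grids at 4x the feature-grid resolution."""

    logits: np.ndarray            # (num_classes, 4h, 4w)
    class_index: dict[str, int]


class TwoWayBlock(Module):
    """One decoder layer: the four attention/FFN stages above."""

    def __init__(self, cfg: DecoderConfig, rng: np.random.Generator):
        self.self_attn = Attention(cfg.embed_dim, cfg.num_heads, rng)
        self.norm1 = LayerNorm(cfg.embed_dim)
        self.cross_attn_token_to_image = Attention(
            cfg.embed_dim, cfg.num_heads, rng, cfg.attention_downsample_rate)
        self.norm2 = LayerNorm(cfg.embed_dim)
        self.mlp = MLPBlock(cfg.embed_dim, cfg.mlp_hidden, rng)
        self.norm3 = LayerNorm(cfg.embed_dim)
        self.cross_attn_image_to_token = Attention(
            cfg.embed_dim, cfg.num_heads, rng, cfg.attention_downsample_rate)
        self.norm4 = LayerNorm(cfg.embed_dim)

    def forward(self, tokens: Tensor, features: Tensor):
        if tokens.shape[-1] != features.shape[-1]:
            raise ShapeError("token/feature dim mismatch at the self-attention stage")
        t = self.norm1(tokens + self.self_attn(tokens, tokens, tokens))
        t = self.norm2(t + self.cross_attn_token_to_image(t, features, features))
        t = self.norm3(t + self.mlp(t))
        src = self.norm4(features + self.cross_attn_image_to_token(features, t, t))
        return t, src


def decoder_layer(tokens, features, block: TwoWayBlock):
    """Apply one two-way layer to (Nt, D) tokens and (h*w, D) features."""
    return block(Tensor.as_tensor(tokens), Tensor.as_tensor(features))


class MaskDecoder(Module):
    def __init__(self, config: DecoderConfig | None = None):
        cfg = config or DecoderConfig()
        self.config = cfg
        rng = np.random.default_rng(cfg.seed)
        E = cfg.embed_dim
        self.iou_token = Parameter(0.02 * rng.standard_normal((1, E)))
        self.mask_tokens = Parameter(0.02 * rng.standard_normal((cfg.num_mask_tokens, E)))
        self.layers = [TwoWayBlock(cfg, rng) for _ in range(cfg.depth)]
        self.final_attn_token_to_image = Attention(
            E, cfg.num_heads, rng, cfg.attention_downsample_rate)
        self.norm_final_attn = LayerNorm(E)
        self.upscale_conv1 = ConvTranspose2x2(E, E // 4, rng)
        self.upscale_norm = LayerNorm2d(E // 4)
        self.upscale_conv2 = ConvTranspose2x2(E // 4, E // 8, rng)
        self.output_hypernetworks_mlps = [
            MLP(E, E, cfg.mask_embed_dim, cfg.head_mlp_depth, rng)
            for _ in range(cfg.num_mask_tokens)
        ]
        # IoU-prediction head of the reference architecture: counted,
        # never used at inference or training here.
        self.iou_prediction_head = MLP(E, E, cfg.num_mask_tokens, cfg.head_mlp_depth, rng)
        self.class_index = {"needle": 0, "tumor": 1}

    # -- API -------------------------------------------------------------------
    def trainable_parameters(self) -> int:
        return self.num_parameters()

    def decode_masks(self, features, prompt: PromptEmbedding) -> tuple[Tensor, MaskLogits]:
        """Decode class mask logits from a feature grid and a box prompt.

        `features` is an (h, w, D) array or Tensor (the frozen encoder
        output). Returns ``(logits_tensor, MaskLogits)`` where the tensor
        carries the autograd graph (num_classes, 4h, 4w).
        """
        cfg = self.config
        feats = features if isinstance(features, Tensor) \
            else Tensor(np.asarray(features, dtype=np.float64))
        if feats.ndim != 3 or feats.shape[2] != cfg.embed_dim:
            raise ShapeError(f"expected (h, w, {cfg.embed_dim}) features, got {feats.shape}")
        if prompt.dense.shape[:2] != feats.shape[:2]:
            raise ShapeError("dense prompt grid does not match the feature grid")
        h, w, E = feats.shape
        batched = self.decode_masks_batch(
            feats.reshape(1, h, w, E),
            Tensor(prompt.sparse).reshape(1, *prompt.sparse.shape),
            Tensor(prompt.dense).reshape(1, h, w, E))
        logits = batched[0]
        return logits, MaskLogits(logits=logits.data, class_index=dict(self.class_index))

    def decode_masks_batch(self, features: Tensor, sparse: Tensor,
                           dense: Tensor) -> Tensor:
        """Batched decode: (B, h, w, D) features + (B, n_corner, D) sparse +
        (B, h, w, D) dense prompts -> (B, num_classes, 4h, 4w) logits."""
        cfg = self.config
        B, h, w, E = features.shape
        src = (features + dense).reshape(B, h * w, E)
        fixed = concat([self.iou_token, self.mask_tokens], axis=0)
        ones = Tensor(np.ones((B, 1, 1)))
        tokens = concat([fixed.reshape(1, 1 + cfg.num_mask_tokens, E) * ones,
                         sparse], axis=1)

        for layer in self.layers:
            tokens, src = layer(tokens, src)
        tokens = self.norm_final_attn(
            tokens + self.final_attn_token_to_image(tokens, src, src))

        grid = src.reshape(B, h, w, E).transpose(0, 3, 1, 2)    # (B, E, h, w)
        up = gelu(self.upscale_norm(self.upscale_conv1(grid)))
        up = gelu(self.upscale_conv2(up))                       # (B, E/8, 4h, 4w)

        up_flat = up.reshape(B, cfg.mask_embed_dim, 4 * h * 4 * w)
        maps = []
        for c in range(cfg.num_classes):
            token_c = tokens[:, 1 + c]                          # (B, E)
            emb = self.output_hypernetworks_mlps[c](token_c)    # (B, E/8)
            m = emb.reshape(B, 1, cfg.mask_embed_dim) @ up_flat
            maps.append(m.reshape(B, 1, 4 * h, 4 * w))
        return concat(maps, axis=1)


def build_decoder(config: DecoderConfig | None = None) -> MaskDecoder:
    return MaskDecoder(config)


def tiny_decoder_config(seed: int = 0) -> DecoderConfig:
    """Unit-test scale decoder (64-dim); not usable with the 256-dim neck."""
    return DecoderConfig(embed_dim=64, num_heads=2, mlp_hidden=512, seed=seed)
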