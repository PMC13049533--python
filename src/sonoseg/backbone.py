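"""Frozen, resolution-agnostic ViT image encoder.

A windowed vision transformer with decomposed per-axis relative positional
terms added to the attention logits, followed by a convolutional neck that
projects to the 256-channel feature space the mask decoder expects. The
encoder is never trained in this package, so it is implemented as a plain
numpy forward pass with an immutability digest.

Because inputs are positioned by the relative terms (interpolated to the
active token grid), any input whose sides are divisible by the patch size
is accepted without resizing. The absolute positional-embedding tensor of
the reference release is kept in the parameter store for checkpoint
compatibility but is not applied.
"""

from __future__ import annotations

import dataclasses
import hashlib

import numpy as np
from scipy import special as _sp

from .errors import ConfigurationError, ShapeError


@dataclasses.dataclass
class EncoderConfig:
    variant: str = "tiny"
    patch_size: int = 16
    embed_dim: int = 64
    depth: int = 2
    num_heads: int = 2
    neck_dim: int = 256
    global_attention_indices: tuple[int, ...] = (1,)
    window_size: int = 8
    base_img_size: int = 256     # grid the stored positional tables refer to
    mlp_ratio: float = 4.0
    init_seed: int = 0

    def __post_init__(self):
        if self.neck_dim != 256:
            raise ConfigurationError("neck_dim must be 256 (decoder feature contract)")
        if self.embed_dim % self.num_heads:
            raise ConfigurationError("embed_dim must divide num_heads")

    @property
    def head_dim(self) -> int:
        return self.embed_dim // self.num_heads


_PRESETS = {
    # test-scale variant; not part of any reference release
    "tiny": dict(embed_dim=64, depth=2, num_heads=2, window_size=8,
                 global_attention_indices=(1,), base_img_size=256),
    # reference configurations of the published promptable-segmentation release
    "vit_b": dict(embed_dim=768, depth=12, num_heads=12, window_size=14,
                  global_attention_indices=(2, 5, 8, 11), base_img_size=1024),
    "vit_l": dict(embed_dim=1024, depth=24, num_heads=16, window_size=14,
                  global_attention_indices=(5, 11, 17, 23), base_img_size=1024),
    "vit_h": dict(embed_dim=1280, depth=32, num_heads=16, window_size=14,
                  global_attention_indices=(7, 15, 23, 31), base_img_size=1024),
}


def encoder_config(variant: str, **overrides) -> EncoderConfig:
    if variant not in _PRESETS:
        raise ConfigurationError(f"unknown encoder variant {variant!r}")
    kw = dict(_PRESETS[variant])
    kw.update(overrides)
    return EncoderConfig(variant=variant, **kw)


@dataclasses.dataclass
class FeatureGrid:
    """Encoder output: an (h, w, 256) grid of feature vectors."""

    features: np.ndarray
    source_size: tuple[int, int]

    def __post_init__(self):
        if not np.all(np.isfinite(self.features)):
            raise ValueError("feature grid contains non-finite entries")

    @property
    def grid_size(self) -> tuple[int, int]:
        return self.features.shape[:2]


def _gelu(x: np.ndarray) -> np.ndarray:
    return 0.5 * x * (1.0 + _sp.erf(x / np.sqrt(2.0)))


def _interp_table(table: np.ndarray, n_needed: int) -> np.ndarray:
    """Linearly resample a (L, d) relative-position table to (n_needed, d)."""
    L = table.shape[0]
    if L == n_needed:
        return table
    xi = np.linspace(0, L - 1, n_needed)
    lo = np.floor(xi).astype(int)
    hi = np.minimum(lo + 1, L - 1)
    frac = (xi - lo)[:, None]
    return table[lo] * (1 - frac) + table[hi] * frac


def _rel_pos_bias(q_hw, table_h, table_w, q, num_heads):
    """Decomposed relative-position term added to attention logits.

    q: (B*heads, N, dh) queries over a (qh, qw) grid; returns the additive
    (B*heads, N, N) bias from per-axis tables.
    """
    qh, qw = q_hw
    Rh = _interp_table(table_h, 2 * qh - 1)
    Rw = _interp_table(table_w, 2 * qw - 1)
    idx_h = np.arange(qh)[:, None] - np.arange(qh)[None, :] + qh - 1
    idx_w = np.arange(qw)[:, None] - np.arange(qw)[None, :] + qw - 1
    Rh = Rh[idx_h]                      # (qh, kh, dh)
    Rw = Rw[idx_w]                      # (qw, kw, dh)
    B = q.shape[0]
    rq = q.reshape(B, qh, qw, -1)
    rel_h = np.einsum("bhwc,hkc->bhwk", rq, Rh)
    rel_w = np.einsum("bhwc,wkc->bhwk", rq, Rw)
    bias = rel_h[:, :, :, :, None] + rel_w[:, :, :, None, :]
    return bias.reshape(B, qh * qw, qh * qw)


class ViTEncoder:
    """Frozen ViT with windowed attention and a 256-channel neck."""

    def __init__(self, config: EncoderConfig, init: str = "random"):
        self.config = config
        self.frozen = False
        self._digest_at_freeze: str | None = None
        self.params: dict[str, np.ndarray] = {}
        self._build(init)

    # -- construction ---------------------------------------------------------
    def _add(self, name: str, shape, rng, init: str, scale: float | None = None):
        if init == "zeros":
            arr = np.zeros(shape, dtype=np.float32)
        else:
            if scale is None:
                fan_in = shape[-1] if len(shape) > 1 else shape[0]
                scale = 1.0 / np.sqrt(fan_in)
            arr = rng.uniform(-scale, scale, size=shape).astype(np.float32)
        self.params[name] = arr

    def _build(self, init: str):
        cfg = self.config
        rng = np.random.default_rng(cfg.init_seed)
        E, p = cfg.embed_dim, cfg.patch_size
        grid = cfg.base_img_size // p
        self._add("patch_embed.proj.weight", (E, 3, p, p), rng, init, 1.0 / np.sqrt(3 * p * p))
        self._add("patch_embed.proj.bias", (E,), rng, init, 1.0 / np.sqrt(3 * p * p))
        # retained for reference-checkpoint compatibility; unused in forward
        self._add("pos_embed", (1, grid, grid, E), rng, "zeros")
        hidden = int(E * cfg.mlp_ratio)
        for i in range(cfg.depth):
            S = grid if i in cfg.global_attention_indices else cfg.window_size
            pre = f"blocks.{i}."
            for ln in ("norm1", "norm2"):
                self.params[pre + ln + ".weight"] = np.ones(E, dtype=np.float32)
                self.params[pre + ln + ".bias"] = np.zeros(E, dtype=np.float32)
            self._add(pre + "attn.qkv.weight", (3 * E, E), rng, init)
            self._add(pre + "attn.qkv.bias", (3 * E,), rng, init, 1.0 / np.sqrt(E))
            self._add(pre + "attn.proj.weight", (E, E), rng, init)
            self._add(pre + "attn.proj.bias", (E,), rng, init, 1.0 / np.sqrt(E))
            self._add(pre + "attn.rel_pos_h", (2 * S - 1, cfg.head_dim), rng, init, 0.02)
            self._add(pre + "attn.rel_pos_w", (2 * S - 1, cfg.head_dim), rng, init, 0.02)
            self._add(pre + "mlp.lin1.weight", (hidden, E), rng, init)
            self._add(pre + "mlp.lin1.bias", (hidden,), rng, init, 1.0 / np.sqrt(E))
            self._add(pre + "mlp.lin2.weight", (E, hidden), rng, init)
            self._add(pre + "mlp.lin2.bias", (E,), rng, init, 1.0 / np.sqrt(hidden))
        D = cfg.neck_dim
        self._add("neck.0.weight", (D, E, 1, 1), rng, init)
        self.params["neck.1.weight"] = np.ones(D, dtype=np.float32)
        self.params["neck.1.bias"] = np.zeros(D, dtype=np.float32)
        self._add("neck.2.weight", (D, D, 3, 3), rng, init, 1.0 / np.sqrt(9 * D))
        self.params["neck.3.weight"] = np.ones(D, dtype=np.float32)
        self.params["neck.3.bias"] = np.zeros(D, dtype=np.float32)

    # -- bookkeeping ----------------------------------------------------------
    def num_parameters(self) -> int:
        return int(sum(v.size for v in self.params.values()))

    def digest(self) -> str:
        h = hashlib.sha256()
        for name in sorted(self.params):
            h.update(name.encode())
            h.update(np.ascontiguousarray(self.params[name]).tobytes())
        return h.hexdigest()

    # -- forward --------------------------------------------------------------
    @staticmethod
    def _ln(x, w, b, eps=1e-6):
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        return (x - mu) / np.sqrt(var + eps) * w + b

    def _attention(self, x: np.ndarray, i: int, window: int | None) -> np.ndarray:
        """(h, w, E) -> (h, w, E); windowed when `window` is given."""
        cfg = self.config
        p = self.params
        h, w, E = x.shape
        if window is not None:
            pad_h = (-h) % window
            pad_w = (-w) % window
            xp = np.pad(x, ((0, pad_h), (0, pad_w), (0, 0)))
            Hp, Wp = xp.shape[:2]
            xp = xp.reshape(Hp // window, window, Wp // window, window, E)
            xw = xp.transpose(0, 2, 1, 3, 4).reshape(-1, window, window, E)
            qh = qw = window
        else:
            xw = x[None]
            Hp = Wp = None
            qh, qw = h, w
        B = xw.shape[0]
        N = qh * qw
        nh, dh = cfg.num_heads, cfg.head_dim
        qkv = xw.reshape(B, N, E) @ p[f"blocks.{i}.attn.qkv.weight"].T \
            + p[f"blocks.{i}.attn.qkv.bias"]
        qkv = qkv.reshape(B, N, 3, nh, dh).transpose(2, 0, 3, 1, 4)
        q, k, v = (a.reshape(B * nh, N, dh) for a in qkv)
        attn = q @ k.transpose(0, 2, 1) / np.sqrt(dh)
        attn += _rel_pos_bias((qh, qw), p[f"blocks.{i}.attn.rel_pos_h"],
                              p[f"blocks.{i}.attn.rel_pos_w"], q, nh)
        attn -= attn.max(axis=-1, keepdims=True)
        attn = np.exp(attn)
        attn /= attn.sum(axis=-1, keepdims=True)
        out = (attn @ v).reshape(B, nh, N, dh).transpose(0, 2, 1, 3).reshape(B, qh, qw, E)
        out = out @ p[f"blocks.{i}.attn.proj.weight"].T + p[f"blocks.{i}.attn.proj.bias"]
        if window is not None:
            out = out.reshape(Hp // window, Wp // window, window, window, E)
            out = out.transpose(0, 2, 1, 3, 4).reshape(Hp, Wp, E)
            out = out[:h, :w]
        else:
            out = out[0]
        return out

    def encode_image(self, image: np.ndarray) -> FeatureGrid:
        """Run the frozen forward pass on one grayscale or RGB image."""
        cfg = self.config
        p = self.params
        img = np.asarray(image, dtype=np.float32)
        if img.ndim == 2:
            img = np.repeat(img[:, :, None], 3, axis=2)
        if img.ndim != 3 or img.shape[2] != 3:
            raise ShapeError("expected (H, W) or (H, W, 3) image")
        H, W = img.shape[:2]
        for axis, size in (("height", H), ("width", W)):
            if size % cfg.patch_size:
                raise ShapeError(
                    f"image {axis} {size} not divisible by patch size {cfg.patch_size}")
        ph, pw = H // cfg.patch_size, W // cfg.patch_size
        ps = cfg.patch_size
        E = cfg.embed_dim
        patches = img.transpose(2, 0, 1).reshape(3, ph, ps, pw, ps)
        patches = patches.transpose(1, 3, 0, 2, 4).reshape(ph * pw, 3 * ps * ps)
        wmat = p["patch_embed.proj.weight"].reshape(E, 3 * ps * ps)
        x = (patches @ wmat.T + p["patch_embed.proj.bias"]).reshape(ph, pw, E)

        hidden = int(E * cfg.mlp_ratio)
        for i in range(cfg.depth):
            win = None if i in cfg.global_attention_indices else cfg.window_size
            pre = f"blocks.{i}."
            y = self._ln(x, p[pre + "norm1.weight"], p[pre + "norm1.bias"])
            x = x + self._attention(y, i, win)
            y = self._ln(x, p[pre + "norm2.weight"], p[pre + "norm2.bias"])
            y = _gelu(y @ p[pre + "mlp.lin1.weight"].T + p[pre + "mlp.lin1.bias"])
            x = x + (y @ p[pre + "mlp.lin2.weight"].T + p[pre + "mlp.lin2.bias"])

        # neck: 1x1 conv -> channel LN -> 3x3 conv (pad 1) -> channel LN
        D = cfg.neck_dim
        x = x @ p["neck.0.weight"].reshape(D, E).T
        x = self._ln(x, p["neck.1.weight"], p["neck.1.bias"])
        xp = np.pad(x, ((1, 1), (1, 1), (0, 0)))
        cols = np.empty((ph, pw, 9 * D), dtype=x.dtype)
        idx = 0
        for di in range(3):
            for dj in range(3):
                cols[:, :, idx * D:(idx + 1) * D] = xp[di:di + ph, dj:dj + pw]
                idx += 1
        w2 = p["neck.2.weight"].transpose(2, 3, 1, 0).reshape(9 * D, D)
        x = cols @ w2
        x = self._ln(x, p["neck.3.weight"], p["neck.3.bias"])
        return FeatureGrid(features=x.astype(np.float64), source_size=(H, W))


def freeze(encoder: ViTEncoder) -> ViTEncoder:
    """Flag the encoder non-trainable and record its immutability digest."""
    encoder.frozen = True
    encoder._digest_at_freeze = encoder.digest()
    return encoder


def count_parameters(model) -> tuple[int, int]:
    """(total, trainable) parameter counts for any model-like object.

    Accepts a :class:`ViTEncoder`, an autograd :class:`~sonoseg.nn.Module`
    or any object exposing ``component_parameter_counts()``.
    """
    from .nn.layers import Module as _Module
    if hasattr(model, "component_parameter_counts"):
        total, trainable = model.component_parameter_counts()
        return total, trainable
    if isinstance(model, ViTEncoder):
        n = model.num_parameters()
        return n, 0 if model.frozen else n
    if isinstance(model, _Module):
        n = model.num_parameters()
        trainable = int(sum(p.size for p in model.parameters() if p.requires_grad))
        return n, trainable
    raise TypeError(f"cannot count parameters of {type(model)!r}")
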