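"""Box prompts: frozen encoding into sparse/dense embeddings, and automatic
box generation at inference time.

A box is encoded as two corner tokens. Each corner's normalized image
coordinate passes through a random-Fourier positional encoding and gains a
learned (frozen) corner-type embedding, giving a 256-dim token per corner.
The dense part of the embedding is a constant "no mask prompt" vector
broadcast over the feature grid. All weights are generated once from a
seed and never trained.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage
from skimage import measure

from .errors import ConfigurationError
from .phantom import tight_box

TARGET_CLASSES = ("needle", "tumor")

#: components smaller than this fall back to the full-image box.
MIN_SALIENT_PIXELS = 20


@dataclasses.dataclass(frozen=True)
class BoxPrompt:
    """Half-open pixel box (x0, y0, x1, y1) in (col, row) order."""

    x0: float
    y0: float
    x1: float
    y1: float
    target_class: str = "needle"

    def canonical(self) -> "BoxPrompt":
        return BoxPrompt(min(self.x0, self.x1), min(self.y0, self.y1),
                         max(self.x0, self.x1), max(self.y0, self.y1),
                         self.target_class)


@dataclasses.dataclass
class PromptEmbedding:
    sparse: np.ndarray   # (2, 256): top-left then bottom-right corner token
    dense: np.ndarray    # (h, w, 256): no-mask default embedding, broadcast

    def __post_init__(self):
        if not (np.all(np.isfinite(self.sparse)) and np.all(np.isfinite(self.dense))):
            raise ValueError("prompt embedding contains non-finite entries")


class PromptEncoder:
    """Frozen prompt encoder (boxes only; points/masks are out of scope).

    The unused mask-downscaling convolution weights of the reference
    architecture are kept in the store so reference checkpoints map
    cleanly and parameter totals match the published counts.
    """

    def __init__(self, embed_dim: int = 256, seed: int = 0):
        if embed_dim % 2:
            raise ConfigurationError("embed_dim must be even")
        self.embed_dim = embed_dim
        self.seed = seed
        rng = np.random.default_rng(seed)
        # positional-encoding matrix is a buffer in the reference release,
        # not a parameter; kept separate from `params` for counting.
        self.pe_gaussian = rng.standard_normal((2, embed_dim // 2))
        self.params: dict[str, np.ndarray] = {}
        for i in range(4):  # point/corner type embeddings (2, 3 = box corners)
            self.params[f"point_embeddings.{i}.weight"] = \
                0.02 * rng.standard_normal((1, embed_dim)).astype(np.float32)
        self.params["not_a_point_embed.weight"] = \
            0.02 * rng.standard_normal((1, embed_dim)).astype(np.float32)
        self.params["no_mask_embed.weight"] = \
            0.02 * rng.standard_normal((1, embed_dim)).astype(np.float32)
        # unused mask-prompt downscaling stack, retained for compatibility
        shapes = {
            "mask_downscaling.0.weight": (4, 1, 2, 2), "mask_downscaling.0.bias": (4,),
            "mask_downscaling.1.weight": (4,), "mask_downscaling.1.bias": (4,),
            "mask_downscaling.3.weight": (16, 4, 2, 2), "mask_downscaling.3.bias": (16,),
            "mask_downscaling.4.weight": (16,), "mask_downscaling.4.bias": (16,),
            "mask_downscaling.6.weight": (256, 16, 1, 1), "mask_downscaling.6.bias": (256,),
        }
        for k, s in shapes.items():
            self.params[k] = 0.02 * rng.standard_normal(s).astype(np.float32)

    def num_parameters(self) -> int:
        return int(sum(v.size for v in self.params.values()))

    def _pe_point(self, x: float, y: float, image_size) -> np.ndarray:
        """Random-Fourier features of a normalized (x, y) position."""
        H, W = image_size
        coords = np.array([(x + 0.5) / W, (y + 0.5) / H]) * 2.0 - 1.0
        proj = 2.0 * np.pi * (coords @ self.pe_gaussian)
        return np.concatenate([np.sin(proj), np.cos(proj)])

    def encode_box(self, box: BoxPrompt, image_size, grid_size) -> PromptEmbedding:
        """Encode one box for an (H, W) image onto an (h, w) feature grid."""
        H, W = image_size
        b = box.canonical()
        if b.x0 == b.x1 or b.y0 == b.y1:
            raise ConfigurationError("degenerate box (zero width or height)")
        if b.x0 < 0 or b.y0 < 0 or b.x1 > W or b.y1 > H:
            raise ConfigurationError("box outside image bounds")
        tl = self._pe_point(b.x0, b.y0, image_size) + self.params["point_embeddings.2.weight"][0]
        br = self._pe_point(b.x1, b.y1, image_size) + self.params["point_embeddings.3.weight"][0]
        sparse = np.stack([tl, br]).astype(np.float64)
        h, w = grid_size
        dense = np.broadcast_to(
            self.params["no_mask_embed.weight"][0].astype(np.float64), (h, w, self.embed_dim)
        ).copy()
        return PromptEmbedding(sparse=sparse, dense=dense)


def auto_box(image: np.ndarray, target_class: str, strategy: str = "full_image") -> BoxPrompt:
    """Generate a prompt box for an unlabeled image.

    ``full_image`` always returns the whole frame. ``saliency`` thresholds
    a class-conditioned intensity rule (needles are bright and elongated,
    lesions are dark and smooth), keeps the largest connected component
    and boxes it; it falls back to the full frame when the component has
    fewer than ``MIN_SALIENT_PIXELS`` pixels.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim == 3:
        img = img.mean(axis=2)
    H, W = img.shape
    full = BoxPrompt(0, 0, W, H, target_class)
    if strategy == "full_image":
        return full
    if strategy != "saliency":
        raise ConfigurationError(f"unknown prompt strategy {strategy!r}")
    if target_class == "needle":
        smooth = ndimage.gaussian_filter(img, 1.0)
        mask = smooth >= np.percentile(smooth, 99.0)
        mask = ndimage.binary_dilation(mask, iterations=3)
    elif target_class == "tumor":
        smooth = ndimage.gaussian_filter(img, 3.0)
        mask = smooth <= np.percentile(smooth, 5.0)
        mask = ndimage.binary_dilation(mask, iterations=2)
    else:
        raise ConfigurationError(f"unknown target class {target_class!r}")
    labels = measure.label(mask)
    if labels.max() == 0:
        return full
    counts = np.bincount(labels.ravel())[1:]
    comp = labels == (int(np.argmax(counts)) + 1)
    if comp.sum() < MIN_SALIENT_PIXELS:
        return full
    x0, y0, x1, y1 = tight_box(comp, margin_px=4)
    return BoxPrompt(x0, y0, x1, y1, target_class)
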