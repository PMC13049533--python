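"""Inference: one unlabeled ultrasound image in, dual predicted masks and a
fused overlay out.

The image is encoded once; a prompt box is generated per class (no ground
truth at inference), the decoder produces per-class logits at 4x the
feature-grid resolution, probabilities are bilinearly resized to the
source resolution and binarized. Images whose sides are not divisible by
the patch size are reflect-padded and the outputs cropped back (or
rejected in strict mode).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import special as _sp

from .errors import ShapeError
from .nn import Tensor, bilinear_resize
from .prompts import BoxPrompt, auto_box


@dataclasses.dataclass
class Prediction:
    probabilities: dict[str, np.ndarray]   # per-class, source resolution
    masks: dict[str, np.ndarray]           # binarized at `threshold`
    boxes: dict[str, tuple]                # prompt boxes actually used
    overlay: np.ndarray                    # (H, W, 3) uint8 fused render
    provenance: dict


def _resize_probs(probs: np.ndarray, out_hw) -> np.ndarray:
    return bilinear_resize(Tensor(probs[None]), out_hw).data[0]


def predict_dual(image, model, prompt_strategy: str = "full_image",
                 threshold: float = 0.5, strict: bool = False,
                 boxes: dict[str, BoxPrompt] | None = None) -> Prediction:
    """Segment both target classes on one grayscale image.

    ``boxes`` overrides automatic prompting (e.g. to evaluate with
    ground-truth boxes); otherwise ``prompt_strategy`` drives
    :func:`~sonoseg.prompts.auto_box` per class.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim == 3:
        img = img.mean(axis=2)
    H, W = img.shape
    patch = model.encoder.config.patch_size
    pad_h = (-H) % patch
    pad_w = (-W) % patch
    if (pad_h or pad_w) and strict:
        raise ShapeError(f"image size {H}x{W} not divisible by patch size {patch} "
                         "(strict mode)")
    padded = np.pad(img, ((0, pad_h), (0, pad_w)), mode="reflect") \
        if (pad_h or pad_w) else img

    grid = model.encoder.encode_image(padded)
    h, w = grid.grid_size
    Hp, Wp = padded.shape

    probs: dict[str, np.ndarray] = {}
    masks: dict[str, np.ndarray] = {}
    used_boxes: dict[str, tuple] = {}
    for cls in model.classes:
        if boxes is not None and cls in boxes:
            box = boxes[cls]
        else:
            box = auto_box(padded, cls, prompt_strategy)
        used_boxes[cls] = (box.x0, box.y0, box.x1, box.y1)
        emb = model.prompt_encoder.encode_box(box, (Hp, Wp), (h, w))
        logits, out = model.decoder.decode_masks(grid.features, emb)
        cls_logits = out.logits[out.class_index[cls]]
        p = _sp.expit(cls_logits)
        p = _resize_probs(p, (Hp, Wp))[:H, :W]
        probs[cls] = p
        masks[cls] = p > threshold

    overlay = fuse_masks(masks.get("needle", np.zeros_like(img, bool)),
                         masks.get("tumor", np.zeros_like(img, bool)), img)
    return Prediction(
        probabilities=probs, masks=masks, boxes=used_boxes, overlay=overlay,
        provenance={"strategy": prompt_strategy, "threshold": threshold,
                    "encoder_digest": model.encoder.digest()[:16],
                    "padded_to": [int(Hp), int(Wp)]},
    )


def fuse_masks(needle_mask, tumor_mask, image) -> np.ndarray:
    """RGB overlay: grayscale base, tumor tinted red, needle tinted green.

    Pixels in both masks render green (needle priority) so the thin
    needle stays visible where it crosses the lesion.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim == 3:
        img = img.mean(axis=2)
    needle = np.asarray(needle_mask, dtype=bool)
    tumor = np.asarray(tumor_mask, dtype=bool)
    if needle.shape != img.shape or tumor.shape != img.shape:
        raise ShapeError("mask and image shapes differ")
    base = np.clip(img, 0, 1)
    rgb = np.stack([base, base, base], axis=-1)
    tumor_only = tumor & ~needle
    rgb[tumor_only] = 0.45 * rgb[tumor_only] + 0.55 * np.array([1.0, 0.1, 0.1])
    rgb[needle] = 0.45 * rgb[needle] + 0.55 * np.array([0.1, 1.0, 0.1])
    return np.clip(np.round(rgb * 255), 0, 255).astype(np.uint8)
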