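"""Composite training objective: weighted BCE + Dice + Focal on mask logits.

    L_total = w_bce·L_bce + w_dice·L_dice + w_focal·L_focal

with the published weighting w = (0.3, 0.4, 0.3). BCE gives pixel-wise
supervision, Dice optimizes region overlap (critical for thin needles),
and Focal (α = 0.8, γ = 2.0) counteracts the severe foreground/background
imbalance of needle masks. Targets for BCE and Dice are label-smoothed,
y ← y(1−2β) + β with β = 0.05, to soften noisy, hazy needle boundaries;
Focal keeps hard {0,1} labels since its p_t is defined for binary targets.

All functions accept logits (pre-sigmoid) and reduce by the mean over
every pixel of the [B, 1, H, W] batch; they take numpy arrays or autograd
tensors and return an autograd scalar (use ``float()`` for the value).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .errors import ConfigurationError, ShapeError
from .nn import Tensor, log, logsigmoid, sigmoid


@dataclasses.dataclass
class LossConfig:
    w_bce: float = 0.3
    w_dice: float = 0.4
    w_focal: float = 0.3
    alpha: float = 0.8
    gamma: float = 2.0
    epsilon: float = 1e-6
    beta: float = 0.05          # label-smoothing strength
    per_sample_dice: bool = False

    def __post_init__(self):
        if min(self.w_bce, self.w_dice, self.w_focal) < 0:
            raise ConfigurationError("loss weights must be >= 0")
        if self.gamma < 0:
            raise ConfigurationError("gamma must be >= 0")
        if not (0.0 <= self.beta < 0.5):
            raise ConfigurationError("beta must be in [0, 0.5)")
        if self.epsilon <= 0:
            raise ConfigurationError("epsilon must be > 0")


def _pair(pred_logits, targets) -> tuple[Tensor, Tensor]:
    p = Tensor.as_tensor(pred_logits)
    t = Tensor.as_tensor(targets)
    if p.shape != t.shape:
        raise ShapeError(f"prediction {p.shape} and target {t.shape} shapes differ")
    return p, t


def smooth_labels(targets, beta: float = 0.05):
    """y(1 − 2β) + β elementwise; β = 0 is the identity."""
    if not (0.0 <= beta < 0.5):
        raise ConfigurationError("beta must be in [0, 0.5)")
    t = Tensor.as_tensor(targets)
    return t * (1.0 - 2.0 * beta) + beta


def bce_loss(pred_logits, targets) -> Tensor:
    """Mean binary cross-entropy on logits, −[y log σ(ŷ) + (1−y) log(1−σ(ŷ))].

    Computed from log σ(ŷ) in log-sum-exp form, so it is finite for any
    finite logit.
    """
    p, t = _pair(pred_logits, targets)
    # log(1-sigmoid(x)) = logsigmoid(x) - x
    ls = logsigmoid(p)
    per_pixel = -(t * ls + (1.0 - t) * (ls - p))
    return per_pixel.mean()


def dice_loss(pred_logits, targets, epsilon: float = 1e-6,
              per_sample: bool = False) -> Tensor:
    """1 − (2 Σ σ(ŷ)y + ε) / (Σ σ(ŷ) + Σ y + ε).

    Sums pool the whole batch by default (matching the single-sum printed
    form); ``per_sample=True`` computes one Dice term per leading-axis
    sample and averages.
    """
    p, t = _pair(pred_logits, targets)
    probs = sigmoid(p)
    if per_sample and p.ndim > 1:
        axes = tuple(range(1, p.ndim))
        inter = (probs * t).sum(axis=axes)
        denom = probs.sum(axis=axes) + t.sum(axis=axes)
        return (1.0 - (2.0 * inter + epsilon) / (denom + epsilon)).mean()
    inter = (probs * t).sum()
    denom = probs.sum() + t.sum()
    return 1.0 - (2.0 * inter + epsilon) / (denom + epsilon)


def focal_loss(pred_logits, targets, alpha: float = 0.8, gamma: float = 2.0) -> Tensor:
    """Mean α (1 − p_t)^γ (−log p_t) with binary targets.

    p_t is σ(ŷ) where y = 1 and 1 − σ(ŷ) where y = 0; α is applied
    uniformly. γ = 0, α = 1 recovers the BCE loss exactly.
    """
    p, t = _pair(pred_logits, targets)
    tv = t.data if isinstance(targets, Tensor) else np.asarray(targets, dtype=float)
    if not np.all((tv == 0) | (tv == 1)):
        raise ShapeError("focal_loss requires hard {0,1} targets")
    probs = sigmoid(p)
    pt = probs * t + (1.0 - probs) * (1.0 - t)
    # stable log p_t: logsigmoid(x) for y=1, logsigmoid(-x) for y=0
    log_pt = logsigmoid(p) * t + logsigmoid(-p) * (1.0 - t)
    per_pixel = alpha * (1.0 - pt) ** gamma * (-log_pt)
    return per_pixel.mean()


def _binary_entropy(y: np.ndarray) -> float:
    """Mean Bernoulli entropy of the targets, the irreducible CE floor."""
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -(np.where(y > 0, y * np.log(y), 0.0)
              + np.where(y < 1, (1 - y) * np.log(1 - y), 0.0))
    return float(h.mean())


def total_loss(pred_logits, targets, config: LossConfig | None = None):
    """Weighted sum of the three components; returns (scalar, breakdown).

    The BCE term consumes label-smoothed targets and is measured in KL
    form — cross-entropy minus the constant entropy of the smoothed
    targets — so it keeps the cross-entropy gradients, equals the plain
    BCE on hard targets, and reaches exactly zero at a perfect fit. Dice
    and Focal consume the hard binary targets (smoothing a region-overlap
    ratio only inflates its floor). The breakdown holds the unweighted
    component values.
    """
    cfg = config or LossConfig()
    p, t = _pair(pred_logits, targets)
    t_smooth = smooth_labels(t, cfg.beta)
    l_bce = bce_loss(p, t_smooth) - _binary_entropy(t_smooth.data)
    l_dice = dice_loss(p, t, cfg.epsilon, cfg.per_sample_dice)
    l_focal = focal_loss(p, t, cfg.alpha, cfg.gamma)
    total = cfg.w_bce * l_bce + cfg.w_dice * l_dice + cfg.w_focal * l_focal
    breakdown = {"bce": float(l_bce), "dice": float(l_dice),
                 "focal": float(l_focal), "total": float(total)}
    return total, breakdown
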