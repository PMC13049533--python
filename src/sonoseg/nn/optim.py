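"""AdamW with decoupled weight decay, plus global-norm gradient clipping."""

from __future__ import annotations

import numpy as np

from ..errors import DivergenceError
from .layers import Parameter


def clip_gradients(params: list[Parameter], max_norm: float) -> float:
    """Scale all gradients so their global L2 norm is at most `max_norm`.

    Returns the pre-clip global norm. Parameters without a gradient are
    skipped. Non-finite gradients raise :class:`DivergenceError`.
    """
    sq = 0.0
    grads = []
    for p in params:
        if p.grad is None:
            continue
        if not np.all(np.isfinite(p.grad)):
            raise DivergenceError("non-finite gradient encountered")
        grads.append(p.grad)
        sq += float((p.grad ** 2).sum())
    norm = float(np.sqrt(sq))
    if norm > max_norm and norm > 0.0:
        scale = max_norm / norm
        for g in grads:
            g *= scale
    return norm


class AdamW:
    def __init__(self, params: list[Parameter], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.01):
        self.params = list(params)
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]
        self._t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self, lr: float | None = None) -> None:
        """One update; parameters with no gradient are left untouched."""
        lr = self.lr if lr is None else lr
        self._t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1 ** self._t
        bc2 = 1.0 - b2 ** self._t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            m *= b1
            m += (1.0 - b1) * p.grad
            v *= b2
            v += (1.0 - b2) * p.grad ** 2
            p.data -= lr * self.weight_decay * p.data  # decoupled decay
            p.data -= lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
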