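"""Desk-scale reference experiments: simulate → adapt → evaluate on a CPU.

These are the package's own reproducible study conditions: a tiny random
backbone (the decoder is the only trained part, as always), the default
easy phantom profile, and a few hundred adaptation steps. Problem sizes
are deliberately small so the full pipeline runs in minutes.
"""

from __future__ import annotations

import dataclasses

from .adapt import TrainConfig, desk_train_config, train
from .metrics import evaluate_dataset
from .model import build_model
from .phantom import PhantomConfig, generate_dataset, split_indices
from .infer import predict_dual


@dataclasses.dataclass
class DeskResult:
    checkpoint: object
    needle_report: object
    tumor_report: object
    loss_initial: float
    loss_final: float
    n_train: int
    n_test: int

    @property
    def loss_ratio(self) -> float:
        return self.loss_final / self.loss_initial


def run_desk_experiment(seed: int = 0, n: int = 60, steps: int = 300,
                        phantom_config: PhantomConfig | None = None,
                        train_config: TrainConfig | None = None,
                        prompt_strategy: str = "saliency") -> DeskResult:
    """Simulate ``n`` phantoms, adapt the decoder, score the held-out split.

    Evaluation runs the full inference path (automatic prompting, no
    ground truth at test time) and reports both the tumor overlap metrics
    and the needle localization metrics in mm.
    """
    pcfg = phantom_config or PhantomConfig(seed=seed)
    samples, _ = generate_dataset(n, pcfg, seed)
    splits = split_indices(n)
    train_samples = [samples[i] for i in splits["train"]]
    test_samples = [samples[i] for i in splits["test"]] or train_samples[-1:]

    model = build_model("tiny", seed=seed)
    tcfg = train_config or desk_train_config(max_steps=steps, seed=seed)
    ckpt = train(train_samples, model, tcfg)

    needle_preds, needle_gts = [], []
    tumor_preds, tumor_gts = [], []
    for s in test_samples:
        pred = predict_dual(s.us_image, model, prompt_strategy=prompt_strategy)
        needle_preds.append(pred.masks["needle"])
        needle_gts.append(s.needle_mask)
        tumor_preds.append(pred.masks["tumor"])
        tumor_gts.append(s.tumor_mask)

    spacing = pcfg.pixel_spacing
    return DeskResult(
        checkpoint=ckpt,
        needle_report=evaluate_dataset(needle_preds, needle_gts, spacing),
        tumor_report=evaluate_dataset(tumor_preds, tumor_gts, spacing),
        loss_initial=ckpt.history[0]["loss"],
        loss_final=ckpt.history[-1]["loss"],
        n_train=len(train_samples),
        n_test=len(test_samples),
    )


def run_overfit_experiment(seed: int = 0, steps: int = 200) -> dict:
    """Single-phantom overfit sanity check; returns the loss trajectory."""
    pcfg = PhantomConfig(seed=seed)
    samples, _ = generate_dataset(1, pcfg, seed)
    model = build_model("tiny", seed=seed)
    tcfg = desk_train_config(max_steps=steps, batch_size=1, seed=seed)
    ckpt = train(samples, model, tcfg)
    h = ckpt.history
    return {"initial": h[0]["loss"], "final": h[-1]["loss"],
            "ratio": h[-1]["loss"] / h[0]["loss"], "history": h}
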