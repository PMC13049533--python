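"""Decoder-only fine-tuning: one joint run over both target classes.

Per batch, images are encoded once by the frozen backbone; each class
contributes a forward pass of the decoder prompted with that class's
ground-truth box, and the composite loss is summed over classes (equal
weight) and averaged over the batch. Only decoder parameters receive
updates — AdamW at the published recipe (lr 1e-4, batch 2, warmup +
cosine decay, global-L2 gradient clip 0.5). Encoder digests are asserted
unchanged after training.

Supervision resolution: ground-truth masks are max-pool-downsampled to
the decoder's native 4x-grid output, keeping thin-needle targets binary
and exactly representable; inference upsamples probabilities back to the
source resolution.
"""

from __future__ import annotations

import dataclasses
import json
import zipfile
from pathlib import Path

import numpy as np

from .backbone import encoder_config
from .decoder import DecoderConfig, MaskDecoder
from .errors import (CheckpointError, ConfigurationError, DivergenceError,
                     SonosegError)
from .losses import LossConfig, total_loss
from .nn import AdamW, Tensor, clip_gradients
from .phantom import PhantomSample, load_manifest
from .prompts import BoxPrompt

CHECKPOINT_VERSION = 1


@dataclasses.dataclass
class TrainConfig:
    epochs: int = 30
    batch_size: int = 2
    base_lr: float = 1e-4
    betas: tuple[float, float] = (0.9, 0.999)
    weight_decay: float = 0.01
    warmup_frac: float = 0.1          # fraction of total steps
    min_lr: float = 0.0
    grad_clip_norm: float = 0.5       # global L2
    seed: int = 0
    classes: tuple[str, ...] = ("needle", "tumor")
    loss: LossConfig = dataclasses.field(default_factory=LossConfig)
    max_steps: int | None = None      # overrides epochs when set (desk scale)

    def __post_init__(self):
        if self.epochs < 1:
            raise ConfigurationError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ConfigurationError("batch_size must be >= 1")
        if self.grad_clip_norm <= 0:
            raise ConfigurationError("grad_clip_norm must be > 0")


def desk_train_config(max_steps: int = 300, batch_size: int = 2,
                      seed: int = 0, **overrides) -> TrainConfig:
    """CPU desk-scale profile for the toy experiments.

    Unlike the default recipe — which fine-tunes from pre-trained decoder
    weights — the desk experiments train a randomly initialized decoder
    behind a tiny random backbone, so a larger base learning rate (1e-3)
    is used and the run is capped at a few hundred steps.
    """
    kw = dict(base_lr=1e-3, max_steps=max_steps, batch_size=batch_size,
              seed=seed)
    kw.update(overrides)
    return TrainConfig(**kw)


@dataclasses.dataclass
class Checkpoint:
    decoder_state: dict[str, np.ndarray]
    class_index: dict[str, int]
    encoder_config: dict
    decoder_config: dict
    prompt_seed: int
    train_config: dict
    history: list[dict]
    encoder_digest: str
    version: int = CHECKPOINT_VERSION


def warmup_cosine_lr(step: int, total_steps: int, config: TrainConfig) -> float:
    """Linear ramp 0 → base_lr over the warmup, then cosine to min_lr.

    `step` counts from 0 (before any update) to `total_steps`; the
    schedule is continuous at the warmup/cosine junction.
    """
    if not (0 <= step <= total_steps):
        raise ConfigurationError(f"step {step} outside [0, {total_steps}]")
    warmup = max(1, int(round(config.warmup_frac * total_steps)))
    if step <= warmup:
        return config.base_lr * step / warmup
    t = (step - warmup) / max(total_steps - warmup, 1)
    return config.min_lr + 0.5 * (config.base_lr - config.min_lr) * (1.0 + np.cos(np.pi * t))


def maxpool_downsample(mask: np.ndarray, factor: int) -> np.ndarray:
    """Binary max-pool: a low-res cell is foreground if any source pixel is."""
    h, w = mask.shape
    if h % factor or w % factor:
        raise ConfigurationError("mask dims must be divisible by the pooling factor")
    return np.asarray(mask, dtype=bool).reshape(
        h // factor, factor, w // factor, factor).any(axis=(1, 3))


def _resolve_samples(dataset) -> list[PhantomSample]:
    if isinstance(dataset, (str, Path)):
        samples, _ = load_manifest(dataset)
        return samples
    return list(dataset)


def train(dataset, model, config: TrainConfig | None = None,
          out_dir=None) -> Checkpoint:
    """Fine-tune the mask decoder on paired phantoms; fully seeded.

    `dataset` is a list of :class:`PhantomSample` or a ``dataset.json``
    path. Returns a checkpoint holding the decoder weights, class-token
    map, config snapshots, per-step loss history and the encoder digest.
    """
    cfg = config or TrainConfig()
    samples = _resolve_samples(dataset)
    if not samples:
        raise ConfigurationError("empty dataset")
    for i, s in enumerate(samples):
        for cls in cfg.classes:
            if getattr(s, f"{cls}_mask", None) is None or cls not in s.boxes:
                raise ConfigurationError(f"sample {i} is missing class {cls!r}")

    encoder = model.encoder
    digest_before = encoder.digest()
    prompt_digest_before = model.prompt_encoder.num_parameters()

    # encode every image once — the encoder is frozen, features never change
    grids = [encoder.encode_image(s.us_image) for s in samples]
    grid_hw = grids[0].grid_size
    image_hw = samples[0].us_image.shape

    # frozen per-class prompt embeddings from the ground-truth boxes
    prompts = []
    for s in samples:
        per_class = {}
        for cls in cfg.classes:
            box = BoxPrompt(*s.boxes[cls], target_class=cls)
            per_class[cls] = model.prompt_encoder.encode_box(box, image_hw, grid_hw)
        prompts.append(per_class)

    # supervision at the decoder's native 4x-grid resolution
    out_factor = image_hw[0] // (4 * grid_hw[0])
    targets = []
    for s in samples:
        per_class = {}
        for cls in cfg.classes:
            m = getattr(s, f"{cls}_mask")
            per_class[cls] = maxpool_downsample(m, out_factor).astype(float)
        targets.append(per_class)

    decoder: MaskDecoder = model.decoder
    class_index = decoder.class_index
    params = decoder.parameters()
    opt = AdamW(params, lr=cfg.base_lr, betas=cfg.betas,
                weight_decay=cfg.weight_decay)

    n = len(samples)
    steps_per_epoch = int(np.ceil(n / cfg.batch_size))
    total_steps = cfg.max_steps or cfg.epochs * steps_per_epoch
    rng = np.random.default_rng(cfg.seed)

    history: list[dict] = []
    order: list[int] = []
    for step in range(total_steps):
        while len(order) < cfg.batch_size:
            order.extend(rng.permutation(n).tolist())
        batch, order = order[:cfg.batch_size], order[cfg.batch_size:]

        opt.zero_grad()
        # one batched decode over every (sample, class) pass of the step
        passes = [(idx, cls) for idx in batch for cls in cfg.classes]
        feats = Tensor(np.stack([grids[i].features for i, _ in passes]))
        sparse = Tensor(np.stack([prompts[i][c].sparse for i, c in passes]))
        dense = Tensor(np.stack([prompts[i][c].dense for i, c in passes]))
        logits = decoder.decode_masks_batch(feats, sparse, dense)

        loss_mean = None
        breakdown_sum = {"bce": 0.0, "dice": 0.0, "focal": 0.0}
        for cls in cfg.classes:
            rows = [r for r, (_, c) in enumerate(passes) if c == cls]
            cls_logits = logits[rows, class_index[cls]]
            tgt = np.stack([targets[i][cls] for i, c in passes if c == cls])
            loss, br = total_loss(cls_logits, tgt, cfg.loss)
            loss_mean = loss if loss_mean is None else loss_mean + loss
            for k in breakdown_sum:
                breakdown_sum[k] += br[k]
        if not np.isfinite(float(loss_mean)):
            if out_dir is not None and history:
                save_checkpoint(_make_checkpoint(model, cfg, history),
                                Path(out_dir) / "last_good.ckpt")
            raise DivergenceError(f"non-finite loss at step {step}")
        loss_mean.backward()
        grad_norm = clip_gradients(params, cfg.grad_clip_norm)
        lr = warmup_cosine_lr(step + 1, total_steps, cfg)
        opt.step(lr=lr)
        history.append({
            "step": step, "lr": lr, "loss": float(loss_mean),
            "grad_norm": grad_norm, **breakdown_sum,
        })

    if encoder.digest() != digest_before:
        raise SonosegError("frozen encoder was modified during training")
    assert model.prompt_encoder.num_parameters() == prompt_digest_before

    ckpt = _make_checkpoint(model, cfg, history)
    if out_dir is not None:
        Path(out_dir).mkdir(parents=True, exist_ok=True)
        save_checkpoint(ckpt, Path(out_dir) / "decoder.ckpt")
        (Path(out_dir) / "history.jsonl").write_text(
            "\n".join(json.dumps(h) for h in history))
    return ckpt


def _make_checkpoint(model, cfg: TrainConfig, history) -> Checkpoint:
    loss_cfg = dataclasses.asdict(cfg.loss)
    train_cfg = dataclasses.asdict(cfg)
    train_cfg["loss"] = loss_cfg
    return Checkpoint(
        decoder_state=model.decoder.state_dict(),
        class_index=dict(model.decoder.class_index),
        encoder_config=dataclasses.asdict(model.encoder.config),
        decoder_config=dataclasses.asdict(model.decoder.config),
        prompt_seed=int(getattr(model.prompt_encoder, "seed", 0)),
        train_config=train_cfg,
        history=list(history),
        encoder_digest=model.encoder.digest(),
    )


# -- serialization ------------------------------------------------------------

def save_checkpoint(ckpt: Checkpoint, path) -> None:
    """Single-file, dependency-free portable format (.npz + JSON meta)."""
    meta = {
        "version": ckpt.version,
        "class_index": ckpt.class_index,
        "encoder_config": ckpt.encoder_config,
        "decoder_config": ckpt.decoder_config,
        "prompt_seed": ckpt.prompt_seed,
        "train_config": ckpt.train_config,
        "history": ckpt.history,
        "encoder_digest": ckpt.encoder_digest,
    }
    arrays = {f"decoder/{k}": v for k, v in ckpt.decoder_state.items()}
    arrays["__meta__"] = np.frombuffer(
        json.dumps(meta, sort_keys=True).encode(), dtype=np.uint8)
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_checkpoint(path) -> Checkpoint:
    path = Path(path)
    try:
        data = np.load(path)
        meta = json.loads(bytes(data["__meta__"]).decode())
    except (zipfile.BadZipFile, KeyError, json.JSONDecodeError, OSError,
            ValueError) as exc:
        raise CheckpointError(f"cannot parse checkpoint {path}: {exc}") from exc
    if meta["version"] != CHECKPOINT_VERSION:
        raise CheckpointError(
            f"checkpoint version {meta['version']} needs migration "
            f"(supported: {CHECKPOINT_VERSION})")
    state = {k[len("decoder/"):]: data[k] for k in data.files if k.startswith("decoder/")}
    return Checkpoint(
        decoder_state=state,
        class_index=meta["class_index"],
        encoder_config=meta["encoder_config"],
        decoder_config=meta["decoder_config"],
        prompt_seed=meta["prompt_seed"],
        train_config=meta["train_config"],
        history=meta["history"],
        encoder_digest=meta["encoder_digest"],
        version=meta["version"],
    )


def model_from_checkpoint(ckpt: Checkpoint):
    """Rebuild the full assembly and load the decoder weights.

    Encoder weights are a deterministic function of the stored config, so
    the stored digest must match the rebuilt encoder exactly.
    """
    from .model import build_model
    from .backbone import EncoderConfig

    enc_cfg = EncoderConfig(**{
        **ckpt.encoder_config,
        "global_attention_indices": tuple(ckpt.encoder_config["global_attention_indices"]),
    })
    dec_cfg = DecoderConfig(**ckpt.decoder_config)
    model = build_model(encoder_cfg=enc_cfg, decoder_cfg=dec_cfg,
                        seed=ckpt.prompt_seed)
    if model.encoder.digest() != ckpt.encoder_digest:
        raise CheckpointError("encoder digest mismatch: checkpoint was trained "
                              "against a different frozen encoder")
    model.decoder.load_state_dict(ckpt.decoder_state)
    model.decoder.class_index = dict(ckpt.class_index)
    return model


def resume_check(ckpt: Checkpoint, model) -> None:
    """Refuse to resume training against a different frozen encoder."""
    if model.encoder.digest() != ckpt.encoder_digest:
        raise CheckpointError("encoder digest mismatch; refusing to resume")


def export_specialized(ckpt: Checkpoint, target_class: str) -> Checkpoint:
    """Single-class view of a joint checkpoint (e.g. a needle-only model)."""
    if target_class not in ckpt.class_index:
        raise ConfigurationError(f"unknown class {target_class!r}")
    view = dataclasses.replace(ckpt)
    view.class_index = {target_class: ckpt.class_index[target_class]}
    return view
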