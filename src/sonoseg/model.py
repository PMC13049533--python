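"""Full model assembly: frozen image encoder + frozen prompt encoder +
trainable mask decoder, plus parameter accounting and the optional
reference-weight loader."""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

from .backbone import EncoderConfig, ViTEncoder, encoder_config, freeze
from .decoder import DecoderConfig, MaskDecoder
from .errors import IncompatibleCheckpointError
from .prompts import PromptEncoder


@dataclasses.dataclass
class DualTargetSegmenter:
    """One promptable segmenter with two class output tokens."""

    encoder: ViTEncoder
    prompt_encoder: PromptEncoder
    decoder: MaskDecoder
    classes: tuple[str, ...] = ("needle", "tumor")

    def component_parameter_counts(self) -> tuple[int, int]:
        enc = self.encoder.num_parameters()
        pe = self.prompt_encoder.num_parameters()
        dec = self.decoder.num_parameters()
        trainable = dec
        if not self.encoder.frozen:
            trainable += enc
        return enc + pe + dec, trainable


def build_model(variant: str = "tiny", encoder_cfg: EncoderConfig | None = None,
                decoder_cfg: DecoderConfig | None = None, seed: int = 0,
                encoder_init: str = "random") -> DualTargetSegmenter:
    """Assemble a segmenter with frozen encoders.

    Weights are a deterministic function of (configs, seed), so a decoder
    checkpoint plus the stored configs reproduces the exact model.
    """
    enc_cfg = encoder_cfg or encoder_config(variant, init_seed=seed)
    encoder = freeze(ViTEncoder(enc_cfg, init=encoder_init))
    prompt_enc = PromptEncoder(embed_dim=enc_cfg.neck_dim, seed=seed)
    decoder = MaskDecoder(decoder_cfg or DecoderConfig(seed=seed))
    return DualTargetSegmenter(encoder=encoder, prompt_encoder=prompt_enc,
                               decoder=decoder)


def load_reference_checkpoint(path, model: DualTargetSegmenter) -> dict:
    """Map reference-release weights (as an .npz state-dict export) onto the
    model, name by name.

    The published checkpoints are torch pickles; export them to ``.npz``
    with their original state-dict keys first (requires torch, outside
    this package). Returns a report with ``loaded`` and ``unmatched`` key
    lists; a shape mismatch raises
    :class:`~sonoseg.errors.IncompatibleCheckpointError` naming the key.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"checkpoint not found: {path}")
    state = dict(np.load(path))
    loaded, unmatched = [], []

    enc_params = model.encoder.params
    pe_params = model.prompt_encoder.params
    dec_params = dict(model.decoder.named_parameters())
    staged: list[tuple[str, dict | None, np.ndarray]] = []
    for key, value in state.items():
        if key.startswith("image_encoder."):
            name = key[len("image_encoder."):]
            target = enc_params.get(name)
            store = enc_params
        elif key.startswith("prompt_encoder."):
            name = key[len("prompt_encoder."):]
            target = pe_params.get(name)
            store = pe_params
        elif key.startswith("mask_decoder."):
            name = key[len("mask_decoder."):]
            target = dec_params.get(name)
            store = None
            if target is not None:
                staged.append((key, {"param": dec_params[name]}, value))
                if value.shape != target.data.shape:
                    raise IncompatibleCheckpointError(
                        f"shape mismatch for {key}: checkpoint {value.shape} "
                        f"vs model {target.data.shape}")
                loaded.append(key)
                continue
            target = None
        else:
            unmatched.append(key)
            continue
        if target is None:
            unmatched.append(key)
            continue
        if value.shape != target.shape:
            raise IncompatibleCheckpointError(
                f"shape mismatch for {key}: checkpoint {value.shape} vs model {target.shape}")
        staged.append((key, {"store": store, "name": name}, value))
        loaded.append(key)

    # apply only after every shape check passed (model untouched on error)
    for key, dest, value in staged:
        if "param" in dest:
            dest["param"].data = np.asarray(value, dtype=np.float64)
        else:
            dest["store"][dest["name"]] = np.asarray(
                value, dtype=dest["store"][dest["name"]].dtype)
    if model.encoder.frozen:
        model.encoder._digest_at_freeze = model.encoder.digest()
    return {"loaded": loaded, "unmatched": unmatched}
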