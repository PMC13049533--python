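# sonoseg

Dual-target promptable segmentation for interventional ultrasound:
one model that simultaneously tracks a biopsy **needle** and delineates a
breast-lesion-like **tumor** on grayscale B-mode-style images, obtained by
fine-tuning *only the mask decoder* of a SAM-style promptable architecture
while the image and prompt encoders stay frozen.

The package is aimed at researchers studying parameter-efficient
adaptation of segmentation foundation models to ultrasound guidance. It
ships everything needed to run the full pipeline on a laptop CPU with no
downloads: a speckle phantom simulator (the needle ground truth is the
*pre-occlusion* geometry, emulating photoacoustic supervision), the
frozen-encoder/trainable-decoder model stack implemented on numpy with a
small built-in autodiff engine, the composite training objective, a
needle-localization metric suite, a seeded training loop, inference with
automatic box prompting, and a thin CLI.

## Model

An image `x` is encoded once by a frozen ViT (16 × 16 patches, relative
positional attention terms, 256-channel neck) into features
`I ∈ R^(H/16 × W/16 × 256)`. A box prompt becomes two 256-d corner tokens
`P`. The trainable two-way transformer decoder (depth 2, 8 heads) runs,
per layer,

    T'   = LN(T   + SelfAttn(T))                  T = [class tokens; P]
    T''  = LN(T'  + CrossAttn(Q=T', K=I, V=I))
    T''' = LN(T'' + MLP(T''))
    I'   = LN(I   + CrossAttn(Q=I, K=T''', V=T'''))

then upsamples `I_final` 4× with two transposed convolutions and forms
per-class logits as `M_logits = MLP(T_final) · I_upsampled` — one output
token per target class, so needle and tumor come out of a single joint
model. Training minimizes

    L = 0.3·L_BCE + 0.4·L_Dice + 0.3·L_Focal      (α = 0.8, γ = 2.0, ε = 1e-6)

with label smoothing `y ← y(1−2β)+β` (β = 0.05) on the BCE term, AdamW at
lr 1e-4 (batch 2, warmup + cosine decay, gradient clipping at L2 norm
0.5), updating the decoder's 4,058,340 parameters only. Evaluation uses
IoU/Dice/precision/recall/pixel accuracy for the tumor and, for the
needle, the modified Hausdorff distance (MHD), targeting error (TE),
localization success rate (NLSR) and length ratio (NLR), all calibrated
to millimetres by the pixel spacing. See `docs/methods.md` for details
and design choices.

## Worked example

`examples/04_desk_experiment.py` runs the reference desk protocol —
simulate 60 phantoms (48 train / 6 val / 6 test), adapt the decoder for
300 steps behind a frozen tiny backbone, evaluate the held-out split
through the automatic-prompting inference path:

```
$ python examples/04_desk_experiment.py
adapted on 48 phantoms, evaluated on 6 held out
loss 1.137 -> 0.213 (19% of initial)

tumor segmentation (held out):
  Dice 0.923 ± 0.016   IoU 0.857   precision 0.887   recall 0.964
needle localization (held out):
  MHD 0.140 mm   TE 0.041 mm   NLSR 100%   NLR 0.983
```

Reading the numbers: tumor Dice 0.923 means the predicted lesion covers
92% of the combined mask area; NLSR 100% means every held-out frame's
needle prediction covers more than half of the thinner mask; MHD and TE
well under 1 mm (at the 0.1 mm/px calibration) say the predicted needle
line lies within a fraction of a millimetre of the true one. The other
examples are smaller: `01` generates and inspects phantoms, `02` shows
the loss and metric definitions on constructed masks, `03` runs a
60-step mini-adaptation.

The same pipeline is scriptable from a shell:

```bash
sonoseg simulate --n 60 --out data/ --seed 0
sonoseg train    --manifest data/dataset.json --out run/ --seed 0 \
                 --config examples/train_config.json
sonoseg predict  --image data/images/0055.png --checkpoint run/decoder.ckpt \
                 --out pred/ --strategy saliency
sonoseg evaluate --pred-dir pred/ --gt-dir gt/ --spacing-mm 0.1 --out report/
```

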