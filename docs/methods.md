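# Methods

## The adaptation model

sonoseg adapts a promptable segmentation architecture to dual-target
interventional ultrasound: one model jointly segments a biopsy needle (a
thin, bright, partially occluded line) and a breast-lesion-like target (an
irregular hypoechoic blob) on grayscale B-mode-style images.

The assembly has three parts:

1. **Image encoder** — a ViT that splits the image into 16 × 16 patches and
   produces an `(H/16, W/16, 256)` feature grid through a convolutional
   neck. Absolute positional embeddings are not applied; instead each
   attention block adds decomposed per-axis relative-position terms to its
   logits, linearly resampled to the active token grid, so any input whose
   sides divide by 16 is encoded at native resolution without resizing.
   The encoder is **frozen**: it is implemented as a plain forward pass,
   its parameters never join the optimizer, and a SHA-256 digest recorded
   at freeze time is asserted unchanged after every training run.
2. **Prompt encoder** (frozen) — a box prompt becomes two 256-d corner
   tokens: random-Fourier features of the normalized corner coordinates
   plus a learned corner-type embedding; the dense prompt is a constant
   "no mask" embedding broadcast over the grid.
3. **Mask decoder** — the only trainable component: a two-way transformer
   of depth 2 with 8 heads and a 2048-wide FFN. Each layer runs four
   residual + layer-norm stages:

       T'   = LN(T   + SelfAttn(T))
       T''  = LN(T'  + CrossAttn(Q=T', K=I, V=I))
       T''' = LN(T'' + MLP(T''))          MLP(x) = W2·GELU(W1 x + b1) + b2
       I'   = LN(I   + CrossAttn(Q=I, K=T''', V=T'''))

   so prompt tokens query the image and the image is re-contextualized by
   the refined tokens. After the layers (plus a final token-to-image
   attention), the image stream is upsampled 4× by two stride-2 transposed
   convolutions, and each class token is mapped by a 3-layer MLP to a
   32-d mask embedding whose per-pixel dot product with the upsampled
   features yields that class's logit map — one output token per class
   (token 0 = needle, token 1 = tumor), decoded at 4× the feature-grid
   resolution and bilinearly resized to the source image at inference.

### Checkpoint-compatibility choices

The decoder keeps the reference release's full token bank (one IoU token,
four mask tokens, the IoU-prediction head) with only the first two mask
tokens class-assigned; the encoder keeps its absolute-positional-embedding
tensor in the parameter store (counted, never applied); the prompt encoder
keeps the unused mask-downscaling convolutions. These unused weights make
`load_reference_checkpoint` a clean name-by-name mapping and keep the
printed architecture totals checkable: 93.7M total / 4,058,340 trainable
for the base assembly, ~0.3B and ~0.6B for the large/huge encoders. The
published checkpoints are torch pickles; the loader consumes an `.npz`
export of the state dict (same keys), produced externally with torch.

### Numerical backend

The package runs entirely on numpy. The frozen encoders are straight
float32 forward passes; the decoder, losses and optimizer run on a small
reverse-mode autodiff engine (`sonoseg.nn`) in float64 — dense arithmetic,
batched matmul, softmax, GELU/sigmoid primitives, and stride-2 transposed
convolutions expressed as reshaped matmuls. Every op's gradient is tested
against central finite differences, and the decoder forward is tested
against a straight-line loop-based re-implementation.

## Training objective

    L_total = 0.3·L_bce + 0.4·L_dice + 0.3·L_focal

- `bce_loss`, `dice_loss` (ε = 1e-6), `focal_loss` (α = 0.8, γ = 2.0)
  implement the standard per-pixel definitions exactly, reduced by the
  mean over all pixels of the batch; Dice pools the whole batch by
  default (`per_sample` available).
- Label smoothing `y ← y(1−2β) + β`, β = 0.05, regularizes against the
  noisy, hazy boundaries of ultrasound needle images.
- **Which terms see smoothed labels.** The BCE term consumes smoothed
  targets and is measured in KL form: cross-entropy minus the (constant)
  entropy of the smoothed targets. Gradients are identical to plain
  cross-entropy, values on hard targets are identical, and a model that
  matches the smoothed targets exactly scores 0 rather than the ~0.2 nats
  of irreducible smoothed-target entropy. Dice and Focal consume hard
  {0,1} targets: Focal's p_t is only defined for binary labels, and
  smoothing a region-overlap ratio merely adds a floor proportional to
  the background area without changing the optimum. Without this
  treatment the composite loss of a perfectly fitted model plateaus near
  30% of its starting value, which would mask real optimization progress.

Training supervises the decoder at its native output resolution: ground
truth masks are max-pool-downsampled by the 4× factor (a low-res cell is
foreground if any of its source pixels is), which keeps one-to-three-pixel
needle targets binary, connected and exactly representable. Evaluation
always happens at source resolution on bilinearly upsampled probabilities,
thresholded at 0.5 (configurable).

## Optimization recipe

Defaults follow the published recipe: AdamW (betas 0.9/0.999, weight
decay 0.01 — unstated upstream, standard defaults), base lr 1e-4, batch 2,
30 epochs, linear warmup over 10% of steps then cosine decay to 0,
gradient clipping at global L2 norm 0.5. Only decoder parameters are
updated; parameters that receive no gradient (IoU head, spare mask-token
MLPs) are skipped entirely, including weight decay. Both classes train in
one joint run: each image is encoded once, each class contributes a
decoder pass prompted by its ground-truth box, and the per-class composite
losses are summed (equal weight) before one backward pass. All batching
across (sample, class) pairs happens inside one graph for speed.

The **desk profile** (`desk_train_config`: lr 1e-3, a few hundred steps)
exists because the desk experiments train a randomly initialized decoder
behind a random tiny backbone from scratch, where the fine-tuning lr of
1e-4 converges far too slowly for a few-minute CPU run. It was fixed from
the single-phantom loss trajectory and is the configuration all examples,
tests and the acceptance script use.

## Synthetic phantoms

No public data ships with the package; `sonoseg.phantom` generates the
study conditions:

- **Speckle** — a smooth tissue field times Rayleigh-like granular noise,
  blended by `speckle_scale` (0.5 default; 0 gives a constant background).
- **Needle** — all pixels within `needle_thickness_px/2` (3 px ≈ an 18G
  needle at the 0.1 mm/px calibration; 2 px ≈ 23G) of a segment drawn at
  −25°…25° from horizontal at 25–75% depth. The *image* rendering drops
  ~16 px chunks with probability `occlusion_prob` (0.15) and casts an
  attenuation shadow below the needle; the *ground-truth* mask is always
  the full pre-occlusion segment, mirroring how photoacoustic supervision
  labels needle regions that the B-mode image hides.
- **Tumor** — a star-shaped (hence connected) blob: an ellipse with radii
  18–40 px whose boundary radius is modulated by 4 random low-order
  harmonics of amplitude `tumor_irregularity` (0.25), rendered darker
  (hypoechoic) with mild internal texture.
- Boxes are tight bounding boxes with a 3 px margin, half-open
  `(x0, y0, x1, y1)` in (col, row) order; 80/10/10 train/val/test split
  (val and test get `floor(n/10)` each, remainder to train). Everything
  is a deterministic function of `(config, seed)`.

Defaults were chosen once so that a small model can overfit a few dozen
samples: high needle contrast, clearly hypoechoic lesions, moderate
occlusion. What passing the desk experiment shows is therefore that the
*pipeline* — encoding, prompting, two-way decoding, the composite loss,
the metric suite — works end to end; it says nothing about clinical
images, whose speckle statistics, artifacts, probe variability and
anatomy the simulator does not attempt to reproduce.

## Evaluation suite

Overlap: IoU, Dice, precision, recall, pixel accuracy (confusion-matrix
trace over total). Conventions for cases the definitions leave open: both
masks empty scores 1 for overlap metrics; an empty denominator with a
non-empty counterpart scores 0.

Needle localization, with mm conversion by the pixel spacing:

- **MHD** = max of the two directed mean nearest-neighbor Euclidean
  distances between the foreground point sets (kd-tree implementation,
  all-pairs oracle in the tests).
- **TE** = |d_abs − d_seg|, the distances from the image center
  (W/2, H/2) to the total-least-squares line fits (principal axis of the
  foreground coordinates) of the true and predicted masks. TLS was chosen
  over RANSAC-style fits for determinism; needles are straight here.
- **NLSR**: success iff the masks intersect and |Sg ∩ Sp| >
  0.5·min(|Sg|, |Sp|), strictly; reported as a percentage of frames.
- **NLR** = predicted/true needle length, length being the extent of the
  foreground projected on its fitted principal axis (not skeleton arc
  length).

Line-based metrics on empty or single-pixel masks raise an
undefined-metric error; the dataset evaluator counts such samples as
failures in a separate tally and never scores them 0.

## Inference

`predict_dual` encodes once, generates one box per class — `full_image`
(trivially valid, the default) or `saliency` (top-percentile brightness
after smoothing for needles, bottom-percentile darkness for lesions,
largest connected component, full-frame fallback under 20 px) — decodes
both class tokens, upsamples probabilities bilinearly, thresholds at 0.5,
and fuses an RGB overlay (needle green over tumor red, needle priority).
Images not divisible by the patch size are reflect-padded and cropped
back, or rejected in strict mode.

## Problem sizes of the shipped experiments

Desk experiment: 60 phantoms (48/6/6 split), tiny backbone (64-d, 2
blocks — a test-scale variant, not part of any reference release), full
256-d decoder, 300 steps, saliency prompting at evaluation. Overfit
check: 1 phantom, 200 steps, batch 1. Reproducibility check: 10 phantoms,
40 steps, run twice. These sizes are the package's reference protocol and
are what `scripts/acceptance.py` and the test suite execute.

## Known limitations

- No pre-trained weights are bundled; desk results use random frozen
  encoders, so absolute segmentation quality is far below what a
  pre-trained backbone would give — the needle Dice in particular is
  limited by the 4×-grid output resolution (a 3 px needle cannot be
  represented sharply at 64×64 logits).
- Single needle, single lesion per frame; no acoustic wave physics, no
  beamforming, no probe-specific artifacts.
- Box prompts only; point and mask prompts are not implemented.
- The IoU-prediction head is carried for weight compatibility but never
  trained or used.
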