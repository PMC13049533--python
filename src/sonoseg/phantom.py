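"""Synthetic ultrasound phantom generator for dual-target segmentation.

Emulates the structure of paired interventional ultrasound data: a bright,
thin, possibly partially occluded metal needle inserted at a shallow angle,
and an irregular hypoechoic (dark) lesion, both embedded in multiplicative
speckle. The needle ground truth is the *pre-occlusion* mask, mirroring the
way photoacoustic supervision reveals needle segments that speckle, shadow
or reverberation hide in the B-mode image: the model is asked to recover
the full needle even where the ultrasound rendering drops it.

Coordinate conventions, used package-wide:
    - arrays are row-major with origin at the top-left;
    - boxes are half-open ``(x0, y0, x1, y1)`` in (column, row) order.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

from .errors import ConfigurationError, EmptyMaskError, GeometryError

#: margin added around each ground-truth mask when deriving its prompt box.
BOX_MARGIN_PX = 3

#: interior darkening factor of the hypoechoic lesion (fraction of background
#: intensity removed inside the blob).
TUMOR_DARKENING = 0.6

Box = tuple[int, int, int, int]


@dataclasses.dataclass
class PhantomConfig:
    """Controls phantom geometry, texture and difficulty.

    Defaults describe an "easy" profile: a high-contrast 18G-like needle
    (about 3 px at 0.1 mm/px) and a clearly hypoechoic lesion, sized so a
    small model can be fit on a few dozen samples on a CPU.
    """

    image_height: int = 256
    image_width: int = 256
    pixel_spacing: float = 0.1           # mm per pixel
    speckle_scale: float = 0.5           # 0 => constant background
    needle_thickness_px: float = 3.0     # "18G" ~ 3 px, "23G" ~ 2 px
    needle_angle_range: tuple[float, float] = (-25.0, 25.0)   # deg from horizontal
    needle_depth_range: tuple[float, float] = (0.25, 0.75)    # row fraction
    needle_contrast: float = 0.55        # additive intensity gain
    occlusion_prob: float = 0.15         # chance a needle chunk is hidden
    shadow_strength: float = 0.35        # attenuation below the needle
    tumor_radius_range: tuple[float, float] = (18.0, 40.0)    # px
    tumor_irregularity: float = 0.25     # boundary perturbation amplitude
    seed: int = 0

    def __post_init__(self):
        if self.image_height < 32 or self.image_width < 32:
            raise ConfigurationError("image dimensions must be >= 32")
        if self.image_height % 16 or self.image_width % 16:
            raise ConfigurationError("image dimensions must be divisible by the 16 px patch size")
        if self.pixel_spacing <= 0:
            raise ConfigurationError("pixel_spacing must be > 0")
        if not (0.0 <= self.occlusion_prob < 1.0):
            raise ConfigurationError("occlusion_prob must be in [0, 1)")
        for name in ("needle_angle_range", "needle_depth_range", "tumor_radius_range"):
            lo, hi = getattr(self, name)
            if hi < lo:
                raise ConfigurationError(f"{name} is empty")


@dataclasses.dataclass
class PhantomSample:
    """One paired record: image, per-class ground truth, prompts, calibration."""

    us_image: np.ndarray                      # (H, W) float in [0, 1]
    needle_mask: np.ndarray                   # (H, W) bool, pre-occlusion
    tumor_mask: np.ndarray                    # (H, W) bool
    needle_endpoints: tuple[tuple[float, float], tuple[float, float]]  # (row, col) pairs
    boxes: dict[str, Box]                     # per-class half-open boxes
    pixel_spacing: float                      # mm / pixel
    seed: int


def render_speckle(config: PhantomConfig, seed: int) -> np.ndarray:
    """Multiplicative speckle background in [0, 1].

    A smooth tissue field multiplied by Rayleigh-like granular noise; the
    product is blended with a flat background by ``speckle_scale`` so a
    scale of 0 yields a spatially constant image. Bit-identical per seed.
    """
    h, w = config.image_height, config.image_width
    rng = np.random.default_rng(seed)
    smooth = ndimage.gaussian_filter(rng.standard_normal((h, w)), sigma=h / 16.0)
    smooth = 1.0 + 0.5 * smooth / max(np.abs(smooth).max(), 1e-12)
    grain = ndimage.gaussian_filter(rng.rayleigh(scale=1.0, size=(h, w)), sigma=1.0)
    grain /= grain.mean()
    texture = smooth * grain
    base = 0.4
    img = base * (1.0 + config.speckle_scale * (texture - 1.0))
    return np.clip(img, 0.0, 1.0)


def _segment_distance(shape: tuple[int, int], p0, p1) -> np.ndarray:
    """Distance from every pixel center to the segment p0-p1 (row, col)."""
    rows, cols = np.mgrid[0:shape[0], 0:shape[1]].astype(float)
    d = np.array(p1, dtype=float) - np.array(p0, dtype=float)
    L2 = float(d @ d)
    t = ((rows - p0[0]) * d[0] + (cols - p0[1]) * d[1]) / L2
    t = np.clip(t, 0.0, 1.0)
    pr = p0[0] + t * d[0]
    pc = p0[1] + t * d[1]
    return np.hypot(rows - pr, cols - pc)


def render_needle(endpoints, config: PhantomConfig, seed: int = 0):
    """Rasterize a needle; returns ``(mask, additive_layer)``.

    `mask` is the full pre-occlusion segment (the supervision target);
    the additive image layer renders only the *visible* sub-segments
    (chunks are dropped with ``occlusion_prob``) plus a darker shadow band
    below the needle. Occlusion therefore affects the image, never the
    ground truth.
    """
    (r0, c0), (r1, c1) = endpoints
    h, w = config.image_height, config.image_width
    for r, c in ((r0, c0), (r1, c1)):
        if not (0 <= r < h and 0 <= c < w):
            raise GeometryError(f"endpoint ({r}, {c}) outside the {h}x{w} image")
    length = np.hypot(r1 - r0, c1 - c0)
    if length == 0:
        raise GeometryError("zero-length needle segment")

    dist = _segment_distance((h, w), (r0, c0), (r1, c1))
    half = config.needle_thickness_px / 2.0
    mask = dist <= half

    # visible part: drop ~16 px chunks along the needle with occlusion_prob
    rng = np.random.default_rng(seed)
    n_chunks = max(1, int(np.ceil(length / 16.0)))
    keep = rng.random(n_chunks) >= config.occlusion_prob
    if config.occlusion_prob == 0.0:
        visible = mask
    else:
        rows, cols = np.mgrid[0:h, 0:w].astype(float)
        t = ((rows - r0) * (r1 - r0) + (cols - c0) * (c1 - c0)) / (length ** 2)
        chunk_idx = np.clip((t * n_chunks).astype(int), 0, n_chunks - 1)
        visible = mask & keep[chunk_idx]

    layer = np.zeros((h, w))
    bright = ndimage.gaussian_filter(visible.astype(float), sigma=0.6)
    layer += config.needle_contrast * bright / max(bright.max(), 1e-12)

    # acoustic shadow: attenuation band beneath the visible needle
    if config.shadow_strength > 0:
        shadow_len = 18
        shade = np.zeros((h, w))
        vis_cols = np.any(visible, axis=0)
        for col in np.nonzero(vis_cols)[0]:
            top = int(np.max(np.nonzero(visible[:, col])[0])) + 2
            lo = min(top, h)
            hi = min(top + shadow_len, h)
            if hi > lo:
                fade = np.linspace(1.0, 0.0, hi - lo)
                shade[lo:hi, col] = fade
        layer -= config.shadow_strength * 0.4 * ndimage.gaussian_filter(shade, sigma=1.0)
    return mask, layer


def render_tumor(center, radii, config: PhantomConfig, seed: int = 0) -> np.ndarray:
    """Simply connected hypoechoic blob mask.

    An ellipse whose boundary radius is modulated by a smooth periodic
    function of polar angle with amplitude ``tumor_irregularity``; the
    region is star-shaped around the center and hence connected.
    """
    h, w = config.image_height, config.image_width
    cr, cc = center
    ry, rx = radii
    if not (0 <= cr < h and 0 <= cc < w):
        raise GeometryError("tumor center outside the image")
    if ry > h or rx > w:
        raise GeometryError("tumor radii larger than the image")
    rng = np.random.default_rng(seed)
    rows, cols = np.mgrid[0:h, 0:w].astype(float)
    dy, dx = rows - cr, cols - cc
    rho = np.sqrt((dy / ry) ** 2 + (dx / rx) ** 2)
    theta = np.arctan2(dy, dx)
    boundary = np.ones_like(theta)
    if config.tumor_irregularity > 0:
        amps = rng.uniform(0.3, 1.0, size=4)
        amps *= config.tumor_irregularity / amps.sum()
        phases = rng.uniform(0, 2 * np.pi, size=4)
        for k, (a, ph) in enumerate(zip(amps, phases), start=2):
            boundary += a * np.cos(k * theta + ph)
        boundary = np.maximum(boundary, 0.1)
    return rho <= boundary


def tight_box(mask: np.ndarray, margin_px: int = 0) -> Box:
    """Axis-aligned half-open box around the mask foreground plus a margin.

    Returns ``(min_col - m, min_row - m, max_col + 1 + m, max_row + 1 + m)``
    clipped to the image bounds.
    """
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise EmptyMaskError("tight_box requires at least one foreground pixel")
    h, w = mask.shape
    m = int(margin_px)
    return (
        max(int(cols.min()) - m, 0),
        max(int(rows.min()) - m, 0),
        min(int(cols.max()) + 1 + m, w),
        min(int(rows.max()) + 1 + m, h),
    )


def _sample_geometry(config: PhantomConfig, rng: np.random.Generator):
    """Draw needle endpoints and tumor (center, radii) for one phantom."""
    h, w = config.image_height, config.image_width
    angle = np.deg2rad(rng.uniform(*config.needle_angle_range))
    depth = rng.uniform(*config.needle_depth_range) * h
    m0 = rng.uniform(0.04, 0.14) * w
    m1 = rng.uniform(0.04, 0.14) * w
    c0, c1 = m0, w - 1 - m1
    half_span = (c1 - c0) / 2.0
    mid_c = (c0 + c1) / 2.0
    r0 = depth - np.tan(angle) * half_span
    r1 = depth + np.tan(angle) * half_span
    pad = config.needle_thickness_px + 2
    r0 = float(np.clip(r0, pad, h - 1 - pad))
    r1 = float(np.clip(r1, pad, h - 1 - pad))

    ry = rng.uniform(*config.tumor_radius_range)
    rx = rng.uniform(*config.tumor_radius_range)
    margin_r = ry * (1 + config.tumor_irregularity) + 2
    margin_c = rx * (1 + config.tumor_irregularity) + 2
    cr = rng.uniform(margin_r, h - 1 - margin_r)
    cc = rng.uniform(margin_c, w - 1 - margin_c)
    return ((r0, c0), (r1, c1)), ((cr, cc), (ry, rx))


def generate_sample(config: PhantomConfig, seed: int) -> PhantomSample:
    """Render one paired phantom; bit-identical for equal (config, seed)."""
    rng = np.random.default_rng(seed)
    needle_ep, (tumor_center, tumor_radii) = _sample_geometry(config, rng)
    sub = rng.integers(0, 2 ** 31, size=4)

    img = render_speckle(config, int(sub[0]))
    tumor = render_tumor(tumor_center, tumor_radii, config, int(sub[1]))

    # hypoechoic interior with mild internal texture
    interior_rng = np.random.default_rng(int(sub[2]))
    interior_noise = ndimage.gaussian_filter(
        interior_rng.standard_normal(img.shape), sigma=1.5)
    img = np.where(tumor, img * (1.0 - TUMOR_DARKENING) * (1.0 + 0.15 * interior_noise), img)

    needle, layer = render_needle(needle_ep, config, int(sub[3]))
    img = np.clip(img + layer, 0.0, 1.0)

    boxes = {
        "needle": tight_box(needle, BOX_MARGIN_PX),
        "tumor": tight_box(tumor, BOX_MARGIN_PX),
    }
    return PhantomSample(
        us_image=img, needle_mask=needle, tumor_mask=tumor,
        needle_endpoints=needle_ep, boxes=boxes,
        pixel_spacing=config.pixel_spacing, seed=int(seed),
    )


def split_indices(n: int, fractions=(0.8, 0.1, 0.1)) -> dict[str, list[int]]:
    """Deterministic train/val/test split of n ordered samples.

    val and test each get ``floor(n * fraction)`` samples (taken from the
    end); train gets the remainder, so n=1 puts the single sample in train.
    """
    n_val = int(np.floor(n * fractions[1]))
    n_test = int(np.floor(n * fractions[2]))
    n_train = n - n_val - n_test
    idx = list(range(n))
    return {
        "train": idx[:n_train],
        "val": idx[n_train:n_train + n_val],
        "test": idx[n_train + n_val:],
    }


def _write_png(path: Path, array: np.ndarray) -> None:
    if array.dtype == bool:
        data = (array * 255).astype(np.uint8)
    else:
        data = np.clip(np.round(array * 255), 0, 255).astype(np.uint8)
    Image.fromarray(data, mode="L").save(path)


def load_png(path) -> np.ndarray:
    """Read an 8-bit grayscale PNG as float in [0, 1]."""
    return np.asarray(Image.open(path).convert("L"), dtype=np.float64) / 255.0


def generate_dataset(n: int, config: PhantomConfig, seed: int,
                     out_dir=None, fractions=(0.8, 0.1, 0.1)):
    """Generate ``n`` phantoms with independent geometry.

    Returns ``(samples, manifest)``. When ``out_dir`` is given, images and
    masks are written as 8-bit PNG and the manifest as ``dataset.json``.
    """
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    ss = np.random.SeedSequence(seed)
    sample_seeds = [int(c.generate_state(1)[0] % (2 ** 31)) for c in ss.spawn(n)]
    samples = [generate_sample(config, s) for s in sample_seeds]
    splits = split_indices(n, fractions)

    records = []
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        try:
            (out_path / "images").mkdir(parents=True, exist_ok=True)
            (out_path / "masks").mkdir(parents=True, exist_ok=True)
        except OSError as exc:
            raise OSError(f"cannot create output directory {out_path}: {exc}") from exc
    for i, smp in enumerate(samples):
        rec = {
            "image": f"images/{i:04d}.png",
            "masks": {"needle": f"masks/{i:04d}_needle.png",
                      "tumor": f"masks/{i:04d}_tumor.png"},
            "boxes": {k: list(map(int, v)) for k, v in smp.boxes.items()},
            "endpoints": [list(map(float, p)) for p in smp.needle_endpoints],
            "pixel_spacing_mm": smp.pixel_spacing,
            "seed": smp.seed,
        }
        records.append(rec)
        if out_path is not None:
            _write_png(out_path / rec["image"], smp.us_image)
            _write_png(out_path / rec["masks"]["needle"], smp.needle_mask)
            _write_png(out_path / rec["masks"]["tumor"], smp.tumor_mask)

    manifest = {"samples": records, "splits": splits,
                "config": dataclasses.asdict(config), "master_seed": int(seed)}
    if out_path is not None:
        (out_path / "dataset.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return samples, manifest


def load_manifest(path):
    """Read ``dataset.json`` and its referenced PNGs back into samples."""
    path = Path(path)
    manifest = json.loads(path.read_text())
    root = path.parent
    samples = []
    for rec in manifest["samples"]:
        samples.append(PhantomSample(
            us_image=load_png(root / rec["image"]),
            needle_mask=load_png(root / rec["masks"]["needle"]) > 0.5,
            tumor_mask=load_png(root / rec["masks"]["tumor"]) > 0.5,
            needle_endpoints=tuple(tuple(p) for p in rec["endpoints"]),
            boxes={k: tuple(v) for k, v in rec["boxes"].items()},
            pixel_spacing=rec["pixel_spacing_mm"],
            seed=rec["seed"],
        ))
    return samples, manifest
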