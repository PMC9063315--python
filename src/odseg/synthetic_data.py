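"""Synthetic neonatal-fundus image generator with ground-truth disc masks.

Emulates the qualitative regime of wide-field RetCam-style fundus
photographs of preterm infants: a reddish-orange background under smooth
uneven illumination, a brighter elliptical optic disc with a
Gaussian-blurred boundary, darker vessel-like curves emanating from the
disc, sensor noise, and a low-contrast "blurred disc" difficulty class.
Scenes render at the native 640 x 480 resolution and are delivered at
256 x 256 (bilinear for the image, nearest-neighbor for the mask so the
ground truth stays binary).

The ground-truth mask is the exact ellipse interior before any blurring;
boundary blur degrades only the image. Disc semi-axes of 25-60 px at
native scale keep the foreground between roughly 0.3% and 6% of pixels —
the small-target regime that motivates the joint Dice+BCE loss.

All appearance constants are generator conventions (the clinical data
this emulates publishes no intensity statistics); they are fixed here and
recorded per sample in the dataset manifest.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage.draw import ellipse as draw_ellipse
from skimage.filters import gaussian
from skimage.transform import AffineTransform, resize, warp

__all__ = [
    "NATIVE_CANVAS",
    "OUTPUT_SIZE",
    "DIFFICULTIES",
    "SceneParams",
    "SegSample",
    "random_scene",
    "generate_sample",
    "generate_dataset",
    "augment",
    "load_manifest",
]

NATIVE_CANVAS = (480, 640)  # rows, cols
OUTPUT_SIZE = (256, 256)
MARGIN = 5  # px clearance between ellipse and canvas border
FOREGROUND_BAND = (0.003, 0.06)  # admissible mask foreground fraction

# appearance constants (native scale)
BACKGROUND_RGB = (0.70, 0.32, 0.16)
DISC_RGB = (0.99, 0.86, 0.55)
VESSEL_RGB = (0.45, 0.12, 0.08)

DIFFICULTIES = {
    # (contrast range, boundary blur sigma range, noise sigma)
    "easy": ((0.65, 1.0), (1.0, 3.0), 0.02),
    "blurred": ((0.15, 0.35), (3.0, 6.0), 0.03),
}


@dataclass
class SceneParams:
    """Full description of one synthetic scene; deterministic given ``seed``."""

    disc_center: tuple  # (row, col) at native scale
    disc_axes: tuple  # semi-axes (a, b), px, each in [25, 60]
    disc_angle: float  # degrees
    disc_contrast: float  # (0, 1]; 1 = obvious disc, small = blurred
    boundary_blur_sigma: float
    n_vessels: int
    illumination: tuple  # (direction degrees, strength in [0, 1))
    noise_sigma: float
    seed: int
    canvas: tuple = NATIVE_CANVAS

    def __post_init__(self):
        if not 0.0 < self.disc_contrast <= 1.0:
            raise ValueError(f"disc_contrast must be in (0, 1], got {self.disc_contrast}")
        h, w = self.canvas
        r, c = self.disc_center
        reach = max(self.disc_axes) + MARGIN
        if not (reach <= r <= h - 1 - reach and reach <= c <= w - 1 - reach):
            raise ValueError("disc ellipse does not fit inside the canvas with a 5 px margin")


@dataclass
class SegSample:
    """Image (3, 256, 256) in [0,1], binary mask (1, 256, 256), provenance."""

    image: np.ndarray
    mask: np.ndarray
    params: SceneParams

    def __post_init__(self):
        frac = float(self.mask.mean())
        lo, hi = FOREGROUND_BAND
        if not lo <= frac <= hi:
            raise ValueError(
                f"mask foreground fraction {frac:.4f} outside the [{lo}, {hi}] band"
            )


def random_scene(seed: int, difficulty: str = "easy") -> SceneParams:
    """Draw scene parameters for one sample from the difficulty's ranges."""
    if difficulty not in DIFFICULTIES:
        raise ValueError(f"unknown difficulty {difficulty!r}; choose from {sorted(DIFFICULTIES)}")
    (c_lo, c_hi), (b_lo, b_hi), noise = DIFFICULTIES[difficulty]
    rng = np.random.default_rng(seed)
    h, w = NATIVE_CANVAS
    axes = tuple(np.round(rng.uniform(25, 60, 2), 1))
    reach = max(axes) + MARGIN + 1
    center = (
        float(np.round(rng.uniform(reach, h - 1 - reach), 1)),
        float(np.round(rng.uniform(reach, w - 1 - reach), 1)),
    )
    return SceneParams(
        disc_center=center,
        disc_axes=axes,
        disc_angle=float(np.round(rng.uniform(0, 180), 1)),
        disc_contrast=float(np.round(rng.uniform(c_lo, c_hi), 3)),
        boundary_blur_sigma=float(np.round(rng.uniform(b_lo, b_hi), 2)),
        n_vessels=int(rng.integers(4, 9)),
        illumination=(
            float(np.round(rng.uniform(0, 360), 1)),
            float(np.round(rng.uniform(0.2, 0.45), 3)),
        ),
        noise_sigma=noise,
        seed=int(seed),
    )


def _ellipse_mask(params: SceneParams) -> np.ndarray:
    h, w = params.canvas
    mask = np.zeros((h, w), dtype=np.uint8)
    rr, cc = draw_ellipse(
        params.disc_center[0], params.disc_center[1],
        params.disc_axes[0], params.disc_axes[1],
        shape=(h, w), rotation=np.deg2rad(params.disc_angle),
    )
    mask[rr, cc] = 1
    return mask


def _illumination_field(params: SceneParams, rng) -> np.ndarray:
    """Smooth multiplicative field: linear gradient plus radial falloff."""
    h, w = params.canvas
    rows, cols = np.mgrid[0:h, 0:w].astype(np.float64)
    theta = np.deg2rad(params.illumination[0])
    strength = params.illumination[1]
    proj = (rows - h / 2) * np.sin(theta) + (cols - w / 2) * np.cos(theta)
    proj /= np.abs(proj).max() + 1e-9
    cr, cc = rng.uniform(0.3, 0.7) * h, rng.uniform(0.3, 0.7) * w
    radial = np.hypot(rows - cr, cols - cc)
    radial /= radial.max()
    field = 1.0 + strength * proj - 0.35 * radial ** 2
    return np.clip(field, 0.25, 1.6)


def _draw_vessels(img: np.ndarray, params: SceneParams, rng) -> None:
    """Darker curvilinear strokes radiating from the disc center (in place)."""
    h, w = params.canvas
    r0, c0 = params.disc_center
    length = 0.9 * max(h, w)
    for _ in range(params.n_vessels):
        ang = rng.uniform(0, 2 * np.pi)
        # quadratic Bezier: start at the disc center, bow sideways, run off-canvas
        end = np.array([r0 + length * np.sin(ang), c0 + length * np.cos(ang)])
        mid = (np.array([r0, c0]) + end) / 2
        mid += rng.uniform(-0.18, 0.18) * length * np.array([np.cos(ang), -np.sin(ang)])
        t = np.linspace(0.0, 1.0, 600)[:, None]
        pts = (1 - t) ** 2 * np.array([r0, c0]) + 2 * t * (1 - t) * mid + t ** 2 * end
        width = int(rng.integers(1, 3))
        depth = rng.uniform(0.5, 0.85)
        for rr, cc in pts:
            ri, ci = int(round(rr)), int(round(cc))
            if not (0 <= ri < h and 0 <= ci < w):
                break
            sl = np.s_[max(ri - width, 0) : ri + width + 1, max(ci - width, 0) : ci + width + 1]
            img[sl] = depth * img[sl] + (1 - depth) * np.asarray(VESSEL_RGB)


def generate_sample(params: SceneParams) -> SegSample:
    """Render one scene; bit-deterministic given ``params`` (incl. seed)."""
    rng = np.random.default_rng(params.seed)
    field = _illumination_field(params, rng)
    img = np.asarray(BACKGROUND_RGB)[None, None, :] * field[..., None]
    img = img * rng.uniform(0.92, 1.08)  # global exposure jitter
    mask = _ellipse_mask(params)
    _draw_vessels(img, params, rng)
    # disc on top of vessels: bright lift, boundary blurred in the image only
    soft = gaussian(mask.astype(np.float64), sigma=params.boundary_blur_sigma)
    alpha = params.disc_contrast * soft[..., None]
    img = img * (1 - alpha) + np.asarray(DISC_RGB)[None, None, :] * alpha
    img = img + rng.normal(0.0, params.noise_sigma, img.shape)
    img = np.clip(img, 0.0, 1.0)
    img_small = resize(img, OUTPUT_SIZE, order=1, anti_aliasing=False, preserve_range=True)
    mask_small = resize(mask, OUTPUT_SIZE, order=0, anti_aliasing=False, preserve_range=True)
    return SegSample(
        image=np.ascontiguousarray(img_small.transpose(2, 0, 1).astype(np.float32)),
        mask=(mask_small > 0.5).astype(np.uint8)[None],
        params=params,
    )


# ---------------------------------------------------------------------------
# datasets on disk


SPLITS = ("train", "val", "test")
MANIFEST_HEADER = "filename,split,seed,center_row,center_col,axis_a,axis_b,angle,contrast"


def _allocate(n: int, fractions) -> list:
    """Floor-then-distribute: floor each share, hand remainders out in order."""
    sizes = [int(np.floor(f * n)) for f in fractions]
    for i in range(n - sum(sizes)):
        sizes[i % len(sizes)] += 1
    return sizes


def _sample_seed(master_seed: int, index: int) -> int:
    return int((master_seed * 1_000_003 + index * 7_919 + 1) % (2**31))


def generate_dataset(
    n: int,
    difficulty_mix: dict | None = None,
    seed: int = 0,
    out_dir=None,
    split_fractions=(0.6, 0.2, 0.2),
):
    """Write ``n`` image/mask PNG pairs plus a manifest CSV under ``out_dir``.

    Layout: ``out_dir/{images,masks}/{train,val,test}/sample_XXXX.png``;
    masks store foreground as 255. Difficulties are allocated by the same
    floor-then-distribute rule as the splits and shuffled deterministically
    so every split sees the mix. Returns the manifest as a list of dicts.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    difficulty_mix = difficulty_mix or {"easy": 0.7, "blurred": 0.3}
    if abs(sum(difficulty_mix.values()) - 1.0) > 1e-9:
        raise ValueError("difficulty mix fractions must sum to 1")
    out_dir = Path(out_dir)
    rng = np.random.default_rng(seed)
    names = sorted(difficulty_mix)
    counts = _allocate(n, [difficulty_mix[k] for k in names])
    difficulties = [d for d, c in zip(names, counts) for _ in range(c)]
    rng.shuffle(difficulties)
    split_sizes = _allocate(n, split_fractions)
    splits = [s for s, c in zip(SPLITS, split_sizes) for _ in range(c)]

    manifest = []
    for i in range(n):
        sp = random_scene(_sample_seed(seed, i), difficulties[i])
        sample = generate_sample(sp)
        split = splits[i]
        fname = f"sample_{i:04d}.png"
        img_dir = out_dir / "images" / split
        msk_dir = out_dir / "masks" / split
        img_dir.mkdir(parents=True, exist_ok=True)
        msk_dir.mkdir(parents=True, exist_ok=True)
        img8 = np.round(sample.image.transpose(1, 2, 0) * 255.0).astype(np.uint8)
        iio.imwrite(img_dir / fname, img8)
        iio.imwrite(msk_dir / fname, (sample.mask[0] * 255).astype(np.uint8))
        manifest.append(
            {
                "filename": fname,
                "split": split,
                "seed": sp.seed,
                "center_row": sp.disc_center[0],
                "center_col": sp.disc_center[1],
                "axis_a": sp.disc_axes[0],
                "axis_b": sp.disc_axes[1],
                "angle": sp.disc_angle,
                "contrast": sp.disc_contrast,
            }
        )
    lines = [MANIFEST_HEADER] + [
        ",".join(str(row[k]) for k in MANIFEST_HEADER.split(",")) for row in manifest
    ]
    (out_dir / "manifest.csv").write_text("\n".join(lines) + "\n")
    return manifest


def load_manifest(root) -> list:
    import csv

    with open(Path(root) / "manifest.csv") as fh:
        return list(csv.DictReader(fh))


# ---------------------------------------------------------------------------
# online augmentation


def augment(
    sample: SegSample,
    seed: int,
    p_flip: float = 0.5,
    p_rotate: float = 0.5,
    p_affine: float = 0.5,
) -> SegSample:
    """Random horizontal flip, small rotation, and small affine transform.

    Identical geometric parameters hit image (bilinear) and mask
    (nearest-neighbor), so the mask stays binary. Rotation is uniform in
    [-10, 10] degrees; the affine draws scale 0.9-1.1, translation up to
    5% per axis, and shear up to 5 degrees. Each transform fires
    independently with its stated probability.
    """
    rng = np.random.default_rng(seed)
    h, w = sample.image.shape[1:]
    tf = AffineTransform()
    if rng.uniform() < p_flip:
        tf = tf + AffineTransform(matrix=np.array([[-1.0, 0, w - 1.0], [0, 1.0, 0], [0, 0, 1.0]]))
    center = AffineTransform(translation=(-(w - 1) / 2, -(h - 1) / 2))
    uncenter = AffineTransform(translation=((w - 1) / 2, (h - 1) / 2))
    if rng.uniform() < p_rotate:
        angle = np.deg2rad(rng.uniform(-10.0, 10.0))
        tf = tf + (center + AffineTransform(rotation=angle) + uncenter)
    if rng.uniform() < p_affine:
        scale = rng.uniform(0.9, 1.1)
        shear = np.deg2rad(rng.uniform(-5.0, 5.0))
        trans = (rng.uniform(-0.05, 0.05) * w, rng.uniform(-0.05, 0.05) * h)
        tf = tf + (center + AffineTransform(scale=scale, shear=shear) + uncenter
                   + AffineTransform(translation=trans))
    img = warp(sample.image.transpose(1, 2, 0).astype(np.float64), tf.inverse,
               order=1, mode="constant", cval=0.0, preserve_range=True)
    msk = warp(sample.mask[0].astype(np.float64), tf.inverse,
               order=0, mode="constant", cval=0.0, preserve_range=True)
    out = SegSample.__new__(SegSample)  # augmentation may move mass off-canvas;
    out.image = np.ascontiguousarray(img.transpose(2, 0, 1).astype(np.float32))
    out.mask = (msk > 0.5).astype(np.uint8)[None]  # skip the band re-check
    out.params = sample.params
    return out
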