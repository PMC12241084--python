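"""Seeded synthetic prostate-like phantoms.

Each phantom is a bright, blurred ellipse (the gland) on a darker
background, optionally decorated with dimmer distractor blobs, a smooth
multiplicative bias field, Gaussian noise and motion blur — the artifact
regime (inhomogeneity, motion, ambiguous boundaries) that makes T2
prostate slices hard to segment. The mask is the rasterised ellipse
*before* blur, noise or bias touch the image, so mask/image geometry is
exact by construction and every downstream module is testable with no
data download.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import convolve as _ndconvolve
from scipy.ndimage import gaussian_filter
from skimage.draw import disk as _sk_disk
from skimage.draw import ellipse as _sk_ellipse

from .imaging_io import ImageSlice, MaskImage, write_nifti, write_png_pair

ARTIFACT_KINDS = ("bias_field", "motion_blur", "rician_noise")


@dataclass(frozen=True)
class PhantomParams:
    """Geometry, contrast and artifact levels of the phantom generator.

    Intensities are arbitrary units in roughly [0, 1]; the defaults give
    a gland/background contrast of 0.6 with mild noise, bias and edge
    blur — a plausible-looking, clearly separable slice.
    """

    image_side: int = 256
    gland_axes_range: tuple[float, float] = (40.0, 80.0)  # semi-axes, px
    gland_intensity: float = 0.8
    background_intensity: float = 0.2
    noise_sigma: float = 0.05
    bias_field_amplitude: float = 0.2
    blur_kernel_sigma: float = 1.5
    n_distractors: int = 0
    distractor_intensity: float = 0.5

    def __post_init__(self):
        if self.image_side <= 0:
            raise ValueError("image_side must be positive")
        lo, hi = self.gland_axes_range
        if not 0 < lo <= hi:
            raise ValueError("gland semi-axes must be positive and ordered")
        if hi >= self.image_side / 2:
            raise ValueError("gland semi-axes must stay below image_side/2")
        if self.noise_sigma < 0 or self.bias_field_amplitude < 0:
            raise ValueError("noise_sigma and bias_field_amplitude must be >= 0")
        if self.blur_kernel_sigma < 0 or self.n_distractors < 0:
            raise ValueError("blur_kernel_sigma and n_distractors must be >= 0")

    @classmethod
    def small(cls, side: int = 64, **overrides) -> "PhantomParams":
        """Desk-scale preset: same appearance at a reduced side."""
        scale = side / 256.0
        kw = dict(image_side=side,
                  gland_axes_range=(40.0 * scale, 80.0 * scale))
        kw.update(overrides)
        return cls(**kw)


@dataclass
class PhantomPair:
    image: ImageSlice
    mask: MaskImage
    seed: int
    params: PhantomParams

    def __post_init__(self):
        if (self.image.height, self.image.width) != (self.mask.height,
                                                     self.mask.width):
            raise ValueError("image and mask dimensions differ")
        if int(self.mask.labels.sum()) == 0:
            raise ValueError("phantom mask has no foreground")


def generate_phantom(params: PhantomParams, seed: int) -> PhantomPair:
    """Deterministically draw one phantom pair for (params, seed)."""
    rng = np.random.default_rng(seed)
    side = params.image_side
    lo, hi = params.gland_axes_range
    a, b = rng.uniform(lo, hi, size=2)
    # centre inside the middle fifth so the gland never clips the border
    cr, cc = rng.uniform(0.4 * side, 0.6 * side, size=2)
    angle = rng.uniform(0.0, np.pi)

    mask = np.zeros((side, side), dtype=np.uint8)
    rr, cc_idx = _sk_ellipse(cr, cc, a, b, shape=mask.shape, rotation=angle)
    mask[rr, cc_idx] = 1
    if mask.sum() == 0:
        raise ValueError("degenerate phantom: rasterised gland is empty")

    img = np.full((side, side), params.background_intensity, dtype=np.float64)
    for _ in range(params.n_distractors):
        r = rng.uniform(0.05, 0.12) * side
        dr, dc = rng.uniform(r, side - r, size=2)
        rr_d, cc_d = _sk_disk((dr, dc), r, shape=img.shape)
        img[rr_d, cc_d] = params.distractor_intensity
    img[mask == 1] = params.gland_intensity

    if params.blur_kernel_sigma > 0:
        img = gaussian_filter(img, params.blur_kernel_sigma, mode="nearest")
    if params.bias_field_amplitude > 0:
        img = apply_artifact(ImageSlice(img), "bias_field",
                             params.bias_field_amplitude,
                             seed=int(rng.integers(2 ** 31))).pixels
    if params.noise_sigma > 0:
        img = img + rng.normal(0.0, params.noise_sigma, img.shape)

    return PhantomPair(image=ImageSlice(img), mask=MaskImage(mask),
                       seed=seed, params=params)


def apply_artifact(image: ImageSlice, kind: str, magnitude: float,
                   seed: int = 0) -> ImageSlice:
    """Apply one imaging artifact; magnitude 0 is the identity.

    * ``bias_field`` — smooth multiplicative inhomogeneity: a random
      low-order 2-D polynomial surface rescaled to exactly [1-m, 1+m];
    * ``motion_blur`` — normalised line kernel of length ~magnitude px
      at a random angle (preserves constants);
    * ``rician_noise`` — magnitude-image noise sqrt((x+σg1)² + (σg2)²)
      with σ = magnitude.
    """
    if kind not in ARTIFACT_KINDS:
        raise ValueError(f"unknown artifact kind {kind!r}; "
                         f"expected one of {ARTIFACT_KINDS}")
    if magnitude < 0:
        raise ValueError("artifact magnitude must be >= 0")
    px = image.pixels
    if magnitude == 0:
        return ImageSlice(px.copy(), spacing=image.spacing)
    rng = np.random.default_rng(seed)

    if kind == "bias_field":
        out = px * _bias_field(px.shape, magnitude, rng)
    elif kind == "motion_blur":
        kernel = _line_kernel(magnitude, rng)
        out = _ndconvolve(px, kernel, mode="nearest")
    else:  # rician_noise
        g1 = rng.normal(0.0, magnitude, px.shape)
        g2 = rng.normal(0.0, magnitude, px.shape)
        out = np.sqrt((px + g1) ** 2 + g2 ** 2)
    return ImageSlice(out, spacing=image.spacing)


def _bias_field(shape, magnitude: float, rng: np.random.Generator) -> np.ndarray:
    h, w = shape
    u = np.linspace(-1.0, 1.0, w)[None, :]
    v = np.linspace(-1.0, 1.0, h)[:, None]
    c = rng.standard_normal(6)
    f = c[0] + c[1] * u + c[2] * v + c[3] * u * v + c[4] * u ** 2 + c[5] * v ** 2
    fmin, fmax = f.min(), f.max()
    if fmax - fmin < 1e-12:
        return np.ones(shape)
    f = 2.0 * (f - fmin) / (fmax - fmin) - 1.0  # exactly [-1, 1]
    return 1.0 + magnitude * f


def _line_kernel(length: float, rng: np.random.Generator) -> np.ndarray:
    n = max(int(round(length)), 1)
    if n == 1:
        return np.ones((1, 1))
    theta = rng.uniform(0.0, np.pi)
    half = n // 2
    size = 2 * half + 1
    kernel = np.zeros((size, size))
    for t in np.linspace(-half, half, 4 * n):
        r = int(round(half + t * np.sin(theta)))
        c = int(round(half + t * np.cos(theta)))
        kernel[r, c] = 1.0
    return kernel / kernel.sum()


def generate_dataset(n: int, params: PhantomParams,
                     split_fractions: tuple[float, float, float] = (0.7, 0.2, 0.1),
                     seed: int = 0) -> dict[str, list[PhantomPair]]:
    """Seeded disjoint train/val/test phantom collections.

    Split sizes are round(n·fraction) for val and test, with the
    remainder going to train, so test/val never exceed their nominal
    share; per-item seeds derive from the master seed.
    """
    fr_train, fr_val, fr_test = split_fractions
    if abs(fr_train + fr_val + fr_test - 1.0) > 1e-6:
        raise ValueError("split fractions must sum to 1")
    n_val = round(n * fr_val)
    n_test = round(n * fr_test)
    n_train = n - n_val - n_test
    for frac, size, name in ((fr_train, n_train, "train"),
                             (fr_val, n_val, "val"), (fr_test, n_test, "test")):
        if frac > 0 and size < 1:
            raise ValueError(f"n={n} leaves the nonempty {name} split with 0 items")

    rng = np.random.default_rng(seed)
    item_seeds = rng.integers(0, 2 ** 31, size=n)
    order = rng.permutation(n)
    pairs = [generate_phantom(params, int(item_seeds[i])) for i in range(n)]
    shuffled = [pairs[i] for i in order]
    return {"train": shuffled[:n_train],
            "val": shuffled[n_train:n_train + n_val],
            "test": shuffled[n_train + n_val:]}


def write_dataset(splits: dict[str, list[PhantomPair]], outdir,
                  *, also_nifti: bool = False) -> Path:
    """Write PNG pairs (16-bit image, 8-bit {0,255} mask) plus a CSV
    manifest (id, image_path, mask_path, split, seed)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = outdir / "manifest.csv"
    with manifest.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "image_path", "mask_path", "split", "seed"])
        idx = 0
        for split, pairs in splits.items():
            for pair in pairs:
                img_p = outdir / f"{split}_{idx:04d}_image.png"
                msk_p = outdir / f"{split}_{idx:04d}_mask.png"
                write_png_pair(pair.image, pair.mask, img_p, msk_p)
                if also_nifti:
                    write_nifti(pair.image.pixels,
                                outdir / f"{split}_{idx:04d}_image.nii.gz")
                writer.writerow([idx, img_p.name, msk_p.name, split, pair.seed])
                idx += 1
    return manifest
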