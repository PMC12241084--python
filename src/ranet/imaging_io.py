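"""Medical-image I/O, intensity/size standardisation and paired
image/mask augmentation.

Volumes are read through the established readers (SimpleITK for
MetaImage, nibabel for NIfTI) and unstacked into 2-D ``ImageSlice``
objects with in-plane spacing from the header. Augmentation follows the
usual family for grayscale MRI: geometric transforms (horizontal /
vertical / diagonal shift, zoom) apply with identical parameters to the
image and the mask (the mask re-binarised after interpolation), while
photometric ones (brightness, contrast, and a gamma analogue of
hue/saturation, which is undefined for single-channel data) touch the
image only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import scipy.ndimage as ndi
from skimage.transform import resize as _sk_resize


class FormatError(ValueError):
    """A file failed to parse under its declared standard."""


class DimensionalityError(ValueError):
    """A volume has a dimensionality this 2-D pipeline does not handle."""


# ---------------------------------------------------------------------
# core containers
# ---------------------------------------------------------------------

@dataclass
class ImageSlice:
    """One 2-D grayscale slice with optional in-plane spacing (mm/pixel)."""

    pixels: np.ndarray
    spacing: tuple[float, float] | None = None

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 1:
            raise ValueError("pixels must be a non-empty 2-D array")
        if not np.isfinite(self.pixels).all():
            raise ValueError("intensities must be finite")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class MaskImage:
    """Binary label map; values strictly {0, 1}."""

    labels: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be 2-D")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("mask values must be strictly {0, 1}")
        self.labels = self.labels.astype(np.uint8)

    @property
    def height(self) -> int:
        return self.labels.shape[0]

    @property
    def width(self) -> int:
        return self.labels.shape[1]


# ---------------------------------------------------------------------
# volume readers / writers
# ---------------------------------------------------------------------

def read_volume(path, format: str | None = None) -> list[ImageSlice]:
    """Read a 3-D volume and unstack it along the third axis.

    ``format`` is ``"mhd"`` or ``"nifti"``; inferred from the suffix when
    omitted. Slice spacing comes from the header's in-plane spacing.
    """
    path = Path(path)
    if format is None:
        s = "".join(path.suffixes).lower()
        if s.endswith(".mhd") or s.endswith(".mha"):
            format = "mhd"
        elif s.endswith(".nii") or s.endswith(".nii.gz"):
            format = "nifti"
        else:
            raise FormatError(f"cannot infer format from {path.name!r}")
    if format == "mhd":
        return _read_mhd(path)
    if format == "nifti":
        return _read_nifti(path)
    raise FormatError(f"unsupported format {format!r}")


def _read_mhd(path: Path) -> list[ImageSlice]:
    import SimpleITK as sitk

    try:
        img = sitk.ReadImage(str(path))
        arr = sitk.GetArrayFromImage(img)  # (z, y, x)
    except RuntimeError as exc:
        raise FormatError(f"failed to parse MetaImage {path.name}: {exc}") from exc
    if arr.ndim != 3:
        raise DimensionalityError(
            f"expected a 3-D volume, got {arr.ndim}-D in {path.name}")
    sx, sy = img.GetSpacing()[:2]
    return [ImageSlice(arr[k].astype(np.float64), spacing=(float(sx), float(sy)))
            for k in range(arr.shape[0])]


def _read_nifti(path: Path) -> list[ImageSlice]:
    import nibabel as nib

    try:
        img = nib.load(str(path))
        arr = np.asanyarray(img.dataobj)
    except Exception as exc:
        raise FormatError(f"failed to parse NIfTI {path.name}: {exc}") from exc
    if arr.ndim != 3:
        raise DimensionalityError(
            f"expected a 3-D volume, got {arr.ndim}-D in {path.name}")
    zooms = img.header.get_zooms()[:2]
    spacing = (float(zooms[0]), float(zooms[1]))
    return [ImageSlice(arr[:, :, k].astype(np.float64), spacing=spacing)
            for k in range(arr.shape[2])]


def write_nifti(volume: np.ndarray, path, spacing=(1.0, 1.0, 1.0)):
    """Write a (H, W, Z) array (or a single slice) as NIfTI."""
    import nibabel as nib

    arr = np.asarray(volume, dtype=np.float32)
    if arr.ndim == 2:
        arr = arr[:, :, None]
    affine = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
    nib.save(nib.Nifti1Image(arr, affine), str(path))
    return Path(path)


def write_mhd(volume: np.ndarray, path, spacing=(1.0, 1.0, 1.0)):
    """Write a (Z, H, W) array as MetaImage (.mhd + .raw)."""
    import SimpleITK as sitk

    img = sitk.GetImageFromArray(np.asarray(volume, dtype=np.float32))
    img.SetSpacing(tuple(float(s) for s in spacing))
    sitk.WriteImage(img, str(path))
    return Path(path)


def write_png_pair(image: ImageSlice, mask: MaskImage, image_path, mask_path):
    """16-bit image PNG (min/max scaled) and 8-bit {0,255} mask PNG."""
    import imageio.v3 as iio

    px = image.pixels
    lo, hi = px.min(), px.max()
    scaled = np.zeros_like(px) if hi == lo else (px - lo) / (hi - lo)
    iio.imwrite(str(image_path), (scaled * 65535).astype(np.uint16))
    iio.imwrite(str(mask_path), (mask.labels * 255).astype(np.uint8))


# ---------------------------------------------------------------------
# standardisation
# ---------------------------------------------------------------------

def resize_and_standardize(slc: ImageSlice, target_side: int = 256) -> ImageSlice:
    """Bilinearly resample to ``target_side`` square, then z-score.

    A constant input maps to all zeros (guarded division). Spacing is
    rescaled by the size change.
    """
    if target_side <= 0:
        raise ValueError("target_side must be positive")
    px = slc.pixels
    if px.shape != (target_side, target_side):
        px = _sk_resize(px, (target_side, target_side), order=1,
                        anti_aliasing=px.shape[0] > target_side,
                        preserve_range=True)
    sd = px.std()
    px = np.zeros_like(px) if sd < 1e-12 else (px - px.mean()) / sd
    spacing = None
    if slc.spacing is not None:
        spacing = (slc.spacing[0] * slc.height / target_side,
                   slc.spacing[1] * slc.width / target_side)
    return ImageSlice(px, spacing=spacing)


def resample_to_spacing(slc: ImageSlice, target_spacing: tuple[float, float]) -> ImageSlice:
    """Resample to a caller-chosen common voxel spacing (mm/pixel)."""
    if slc.spacing is None:
        raise ValueError("slice has no spacing metadata to resample from")
    factors = (slc.spacing[0] / target_spacing[0],
               slc.spacing[1] / target_spacing[1])
    new_shape = (max(1, round(slc.height * factors[0])),
                 max(1, round(slc.width * factors[1])))
    px = _sk_resize(slc.pixels, new_shape, order=1, preserve_range=True,
                    anti_aliasing=factors[0] < 1)
    return ImageSlice(px, spacing=tuple(target_spacing))


# ---------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------

@dataclass
class AugmentationPlan:
    """Switches and magnitude ranges for the augmentation family.

    A range with equal endpoints pins the magnitude (useful for tests);
    ``hue_mode='noop'`` disables the grayscale gamma analogue while
    keeping the switch surface intact.
    """

    horizontal_shift: bool = False
    vertical_shift: bool = False
    diagonal_shift: bool = False
    zoom: bool = False
    hue_saturation: bool = False
    random_brightness: bool = False
    random_contrast: bool = False
    shift_range: tuple[float, float] = (-10.0, 10.0)  # pixels
    zoom_range: tuple[float, float] = (-0.1, 0.1)  # fractional
    brightness_range: tuple[float, float] = (-0.2, 0.2)  # fraction of dynamic range
    contrast_range: tuple[float, float] = (-0.2, 0.2)
    gamma_range: tuple[float, float] = (-0.2, 0.2)
    hue_mode: str = "gamma"  # {"gamma", "noop"}
    seed: int = 0

    def __post_init__(self):
        for name in ("shift_range", "zoom_range", "brightness_range",
                     "contrast_range", "gamma_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} is not a valid range: ({lo}, {hi})")
        if self.hue_mode not in ("gamma", "noop"):
            raise ValueError(f"unknown hue_mode {self.hue_mode!r}")


def _rebinarize(arr: np.ndarray) -> np.ndarray:
    return (arr > 0.5).astype(np.uint8)


def augment_pair(image: ImageSlice, mask: MaskImage,
                 plan: AugmentationPlan) -> tuple[ImageSlice, MaskImage]:
    """Apply the plan; geometric ops hit image and mask identically,
    photometric ops the image only. Deterministic for a fixed seed."""
    if (image.height, image.width) != (mask.height, mask.width):
        raise ValueError("image and mask dimensions differ")
    rng = np.random.default_rng(plan.seed)
    px = image.pixels.copy()
    lb = mask.labels.astype(np.float64)

    dx = dy = 0.0
    if plan.horizontal_shift:
        dx += rng.uniform(*plan.shift_range)
    if plan.vertical_shift:
        dy += rng.uniform(*plan.shift_range)
    if plan.diagonal_shift:
        # equal-magnitude simultaneous horizontal + vertical shift
        d = rng.uniform(*plan.shift_range)
        dx += d
        dy += d
    if max(abs(dx), abs(dy)) >= min(image.height, image.width):
        raise ValueError(f"shift ({dy:.1f}, {dx:.1f}) px exceeds the image size")
    if dx or dy:
        px = ndi.shift(px, (dy, dx), order=1, mode="constant", cval=0.0)
        lb = ndi.shift(lb, (dy, dx), order=1, mode="constant", cval=0.0)

    if plan.zoom:
        f = 1.0 + rng.uniform(*plan.zoom_range)
        px = _center_zoom(px, f, order=1)
        lb = _center_zoom(lb, f, order=1)

    lb = _rebinarize(lb)

    rng_max, rng_min = px.max(), px.min()
    dyn = rng_max - rng_min
    if plan.random_brightness:
        px = px + rng.uniform(*plan.brightness_range) * (dyn if dyn > 0 else 1.0)
    if plan.random_contrast:
        c = 1.0 + rng.uniform(*plan.contrast_range)
        px = px.mean() + (px - px.mean()) * c
    if plan.hue_saturation and plan.hue_mode == "gamma" and dyn > 0:
        g = 1.0 + rng.uniform(*plan.gamma_range)
        lo, hi = px.min(), px.max()
        if hi > lo:
            px = lo + (hi - lo) * ((px - lo) / (hi - lo)) ** g

    return ImageSlice(px, spacing=image.spacing), MaskImage(lb)


def _center_zoom(arr: np.ndarray, factor: float, *, order: int) -> np.ndarray:
    """Zoom about the image centre, keeping the output shape."""
    h, w = arr.shape
    matrix = np.array([[1.0 / factor, 0.0], [0.0, 1.0 / factor]])
    centre = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    offset = centre - matrix @ centre
    return ndi.affine_transform(arr, matrix, offset=offset, order=order,
                                mode="constant", cval=0.0)


def plan_from_dict(d: dict) -> AugmentationPlan:
    """Build a plan from a config mapping mirroring the field names."""
    return AugmentationPlan(**{k: tuple(v) if isinstance(v, list) else v
                               for k, v in d.items()})


def plan_to_dict(plan: AugmentationPlan) -> dict:
    return asdict(plan)
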