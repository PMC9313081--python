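"""Image I/O, oocyte cropping, and mirror/rotation augmentation.

Coordinate convention: arrays are row-major with the origin at the top-left;
rotation angles are counter-clockwise.  Multiples of 90 degrees are applied
losslessly with array transposes; other angles use bilinear interpolation with
zero fill (inert, because the background outside the mask is already zeroed by
cropping).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

from .errors import ConfigurationError, ValidationError
from .synthetic_oocytes import SyntheticOocyte


@dataclass
class OocyteImage:
    """One (possibly transformed) oocyte record.

    ``source_id`` identifies the biological oocyte and is conserved through
    cropping and augmentation, so grouped splits can prevent leakage between
    augmented copies of the same cell.
    """

    pixels: np.ndarray
    mask: np.ndarray
    group: str = "unlabeled"
    source_id: str = ""
    transform_tag: str = "original"
    latent_age: str | None = None

    def __post_init__(self) -> None:
        if self.pixels.shape != self.mask.shape:
            raise ValidationError(
                f"pixels shape {self.pixels.shape} != mask shape {self.mask.shape} "
                f"for source {self.source_id!r}"
            )


@dataclass(frozen=True)
class TransformSet:
    """Ordered, unique (mirror, rotation-angle) pairs; includes identity by default."""

    transforms: tuple[tuple[bool, float], ...] = field(
        default_factory=lambda: ((False, 0.0), (False, 45.0), (False, 90.0),
                                 (True, 0.0), (True, 45.0), (True, 90.0)))

    def __post_init__(self) -> None:
        if len(self.transforms) == 0:
            raise ConfigurationError("transform set must be non-empty")
        if len(set(self.transforms)) != len(self.transforms):
            raise ConfigurationError("transform set entries must be unique")

    def __len__(self) -> int:
        return len(self.transforms)

    def __iter__(self):
        return iter(self.transforms)


def default_transform_set() -> TransformSet:
    """{identity, mirror} x {0, 45, 90} degrees — a 6-fold expansion."""
    return TransformSet()


def _read_image(path: Path) -> np.ndarray:
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    if path.suffix.lower() in (".tif", ".tiff"):
        return np.asarray(tifffile.imread(path))
    return np.asarray(iio.imread(path))


def load_cohort(manifest_path: str | Path) -> list[OocyteImage]:
    """Read a cohort manifest and its images/masks.

    Intensities are rescaled per image to [0, 1] by dividing by the image
    maximum; masks become boolean.  Paths in the manifest are resolved
    relative to the manifest's directory.
    """
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise FileNotFoundError(f"manifest not found: {manifest_path}")
    root = manifest_path.parent
    table = pd.read_csv(manifest_path)
    images: list[OocyteImage] = []
    for row in table.itertuples(index=False):
        img = _read_image(root / row.image_path).astype(np.float64)
        mask_path = root / row.mask_path
        if not mask_path.exists():
            raise FileNotFoundError(f"mask file not found: {mask_path}")
        mask = np.asarray(iio.imread(mask_path)) > 0
        if img.shape != mask.shape:
            raise ValidationError(
                f"image {row.image_path} shape {img.shape} does not match "
                f"mask {row.mask_path} shape {mask.shape}"
            )
        peak = img.max()
        if peak > 0:
            img = img / peak
        latent = getattr(row, "latent_age", None)
        images.append(OocyteImage(pixels=img, mask=mask, group=str(row.group),
                                  source_id=str(row.source_id),
                                  transform_tag="original",
                                  latent_age=None if latent is None else str(latent)))
    return images


def from_synthetic(oocytes: Iterable[SyntheticOocyte]) -> list[OocyteImage]:
    """Wrap in-memory synthetic oocytes without a file round-trip."""
    return [OocyteImage(pixels=oo.pixels.copy(), mask=oo.mask.copy(),
                        group=oo.group, source_id=oo.source_id,
                        transform_tag="original", latent_age=oo.latent_age)
            for oo in oocytes]


def crop_to_oocyte(image: OocyteImage, pad: int = 0) -> OocyteImage:
    """Crop to the mask's bounding box (+pad), zero the background, square up.

    The square is obtained by extending the shorter bounding-box side, clipped
    to the original image bounds; pixels outside the mask are set to zero.
    """
    if not image.mask.any():
        raise ValidationError(f"empty mask for source {image.source_id!r}")
    rows = np.flatnonzero(image.mask.any(axis=1))
    cols = np.flatnonzero(image.mask.any(axis=0))
    r0, r1 = rows[0] - pad, rows[-1] + pad + 1
    c0, c1 = cols[0] - pad, cols[-1] + pad + 1
    H, W = image.mask.shape

    def widen(lo: int, hi: int, target: int, limit: int) -> tuple[int, int]:
        extra = target - (hi - lo)
        lo -= extra // 2
        hi += extra - extra // 2
        if lo < 0:
            hi += -lo
            lo = 0
        if hi > limit:
            lo -= hi - limit
            hi = limit
        return max(lo, 0), min(hi, limit)

    side = max(r1 - r0, c1 - c0)
    r0, r1 = widen(max(r0, 0), min(r1, H), side, H)
    c0, c1 = widen(max(c0, 0), min(c1, W), side, W)
    sub_mask = image.mask[r0:r1, c0:c1]
    sub = np.where(sub_mask, image.pixels[r0:r1, c0:c1], 0.0)
    return replace(image, pixels=sub, mask=sub_mask.copy())


def resize_to(image: OocyteImage, side: int) -> OocyteImage:
    """Resample to ``side`` x ``side`` (bilinear for pixels, nearest for mask)."""
    from skimage.transform import resize

    px = resize(image.pixels, (side, side), order=1, anti_aliasing=True,
                preserve_range=True)
    mk = resize(image.mask.astype(float), (side, side), order=0,
                preserve_range=True) > 0.5
    return replace(image, pixels=px, mask=mk)


def _apply_transform(pixels: np.ndarray, mirror: bool, angle: float,
                     order: int) -> np.ndarray:
    out = np.fliplr(pixels) if mirror else pixels
    angle = float(angle) % 360.0
    if angle == 0.0:
        return out.copy()
    if angle % 90.0 == 0.0:
        return np.ascontiguousarray(np.rot90(out, k=int(angle // 90)))
    return ndimage.rotate(out, angle, reshape=False, order=order, mode="constant",
                          cval=0.0)


def transform_tag(mirror: bool, angle: float) -> str:
    return ("mirror+" if mirror else "") + f"rot{int(round(angle)):03d}"


def augment(images: Sequence[OocyteImage],
            transforms: TransformSet | None = None) -> list[OocyteImage]:
    """Expand a cohort by every (mirror, rotation) in ``transforms``.

    Output length is exactly ``len(images) * len(transforms)``; each record
    keeps its parent's group, source_id, and latent age, and carries a
    descriptor of the transform applied.  Mirrors are applied before rotation;
    rotation is about the image center.
    """
    if transforms is None:
        transforms = default_transform_set()
    if len(transforms) == 0:
        raise ConfigurationError("transform set must be non-empty")
    out: list[OocyteImage] = []
    for image in images:
        if image.transform_tag != "original":
            raise ValidationError(
                f"augment expects original images; got {image.transform_tag!r} "
                f"for source {image.source_id!r}"
            )
        for mirror, angle in transforms:
            px = _apply_transform(image.pixels, mirror, angle, order=1)
            mk = _apply_transform(image.mask.astype(float), mirror, angle,
                                  order=0) > 0.5
            out.append(replace(image, pixels=px, mask=mk,
                               transform_tag=transform_tag(mirror, angle)))
    return out


def auto_segment(pixels: np.ndarray) -> np.ndarray:
    """Convenience threshold-based segmenter (largest dark connected blob).

    Not the reference path — masks normally arrive as files — but useful for
    images lacking one.
    """
    from skimage.filters import threshold_otsu
    from skimage.measure import label

    dev = np.abs(pixels - np.median(pixels))
    fg = dev > threshold_otsu(dev)
    # bridge the bright perivitelline annulus between cytoplasm and zona ring
    fg = ndimage.binary_closing(fg, iterations=6)
    lab = label(fg)
    if lab.max() == 0:
        raise ValidationError("auto segmentation found no foreground")
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    keep = lab == sizes.argmax()
    return ndimage.binary_fill_holes(keep)
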