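"""Synthetic brightfield-like oocyte images with controllable age effects.

The generator emulates the three study cohorts (young, old, treated) as
concentric elliptical structures on a bright background: a textured cytoplasm
disk, a brighter perivitelline annulus, and a darker zona pellucida ring.
Age-related differences are encoded as simultaneous shifts of texture
granularity, zona thickness, perivitelline gap, and ellipticity, all scaled by
a single ``effect_size`` dial.  The treated cohort is a latent mixture of
young-like and old-like morphologies.

Cytoplasmic texture is a stationary Gaussian random field (low-pass filtered
white noise with one correlation length); sensor noise is additive Gaussian,
matching the cooled-camera regime of the emulated instrument.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

from ._utils import derive_seed
from .errors import ConfigurationError, GeometryError

GROUPS = ("young", "old", "treated")

# Brightfield intensity plateaus (fractions of full scale).
_BG = 0.82
_CYTO = 0.50
_PERIV = 0.78
_ZONA = 0.62


@dataclass(frozen=True)
class CohortSpec:
    """Sizes and mixing of the three simulated cohorts.

    ``effect_size`` multiplies every class-mean morphological difference;
    0 makes young and old identically distributed.  ``p_young_in_treated`` is
    the latent probability that a treated oocyte retains young-like morphology.
    """

    n_young: int = 26
    n_old: int = 21
    n_treated: int = 29
    p_young_in_treated: float = 0.6
    effect_size: float = 1.0
    image_side: int = 256
    seed: int = 0

    def validate(self) -> None:
        for field in ("n_young", "n_old", "n_treated"):
            if int(getattr(self, field)) < 0:
                raise ConfigurationError(f"{field} must be >= 0, got {getattr(self, field)}")
        if not (0.0 <= self.p_young_in_treated <= 1.0):
            raise ConfigurationError(
                f"p_young_in_treated must be in [0, 1], got {self.p_young_in_treated}"
            )
        if self.effect_size < 0:
            raise ConfigurationError(f"effect_size must be >= 0, got {self.effect_size}")
        if self.image_side < 64:
            raise ConfigurationError(f"image_side must be >= 64, got {self.image_side}")


@dataclass(frozen=True)
class MorphologyParams:
    """Geometric and textural parameters of one oocyte class (pixel units)."""

    oocyte_radius_mean: float = 78.0
    ellipticity: float = 1.06
    zona_thickness: float = 10.0
    perivitelline_gap: float = 5.0
    texture_corr_length: float = 6.0
    texture_amplitude: float = 0.08
    noise_sd: float = 0.01

    def validate(self) -> None:
        for field in ("oocyte_radius_mean", "zona_thickness", "perivitelline_gap",
                      "texture_corr_length"):
            if getattr(self, field) <= 0:
                raise ConfigurationError(f"{field} must be > 0, got {getattr(self, field)}")
        if self.ellipticity < 1.0:
            raise ConfigurationError(f"ellipticity must be >= 1, got {self.ellipticity}")
        if self.texture_amplitude < 0 or self.noise_sd < 0:
            raise ConfigurationError("texture_amplitude and noise_sd must be >= 0")
        if self.texture_corr_length >= self.oocyte_radius_mean:
            raise ConfigurationError(
                "texture_corr_length must be smaller than oocyte_radius_mean"
            )


@dataclass
class SyntheticOocyte:
    pixels: np.ndarray  # float64 in [0, 1], shape (side, side)
    mask: np.ndarray  # bool, same shape; True inside the zona outer boundary
    group: str
    latent_age: str  # "young-like" | "old-like"
    source_id: str


# Per-axis half-differences applied at effect_size = 1; young gets "+", old "-".
_DELTAS = {
    "texture_corr_length": -1.5,  # young cytoplasm: finer granularity
    "zona_thickness": +1.5,  # young zona: slightly thicker ring
    "perivitelline_gap": -1.0,  # young: smaller perivitelline space
    "ellipticity": -0.04,  # young: rounder outline
}


def class_params(base: MorphologyParams, group: str, effect_size: float) -> MorphologyParams:
    """Shift ``base`` along the four default morphology axes for one class.

    Young and old receive symmetric opposite shifts scaled by ``effect_size``;
    at 0 both classes coincide with ``base``.  Values are clipped to stay valid.
    """
    sign = {"young": +1.0, "old": -1.0}[group]
    kw = dataclasses.asdict(base)
    for field, half in _DELTAS.items():
        kw[field] = kw[field] + sign * half * effect_size
    kw["ellipticity"] = max(kw["ellipticity"], 1.0)
    kw["texture_corr_length"] = max(kw["texture_corr_length"], 1.0)
    kw["zona_thickness"] = max(kw["zona_thickness"], 1.0)
    kw["perivitelline_gap"] = max(kw["perivitelline_gap"], 0.5)
    params = MorphologyParams(**kw)
    params.validate()
    return params


def default_class_params(
    effect_size: float, base: MorphologyParams | None = None,
) -> tuple[MorphologyParams, MorphologyParams]:
    """(young, old) parameter pair at the given effect size."""
    if base is None:
        base = MorphologyParams()
    return (class_params(base, "young", effect_size),
            class_params(base, "old", effect_size))


def render_oocyte(
    params: MorphologyParams,
    rng: np.random.Generator,
    image_side: int = 256,
    group: str = "young",
    latent_age: str = "young-like",
    source_id: str = "oocyte",
) -> SyntheticOocyte:
    """Render one oocyte: concentric ellipses + correlated texture + noise.

    The per-oocyte radius, orientation, and center are jittered from ``rng`` so
    the cohort has natural within-class variability.  With
    ``texture_amplitude = 0`` and ``noise_sd = 0`` the image is piecewise
    constant (exact plateaus), which the tests exploit.
    """
    params.validate()
    s = int(image_side)
    r = params.oocyte_radius_mean * (1.0 + 0.04 * rng.standard_normal())
    theta = rng.uniform(0.0, np.pi)
    cx = s / 2.0 + rng.uniform(-3.0, 3.0)
    cy = s / 2.0 + rng.uniform(-3.0, 3.0)
    # texture/sensor noise fields are always drawn so the stream is aligned
    # across parameter settings
    tex_white = rng.standard_normal((s, s))
    sens = rng.standard_normal((s, s))

    e = params.ellipticity
    a_c = r * np.sqrt(e)  # cytoplasm semi-axes
    b_c = r / np.sqrt(e)
    g = params.perivitelline_gap
    t = params.zona_thickness
    outer = max(a_c, b_c) + g + t
    if (cy - outer < 1.0 or cx - outer < 1.0 or cy + outer > s - 2.0
            or cx + outer > s - 2.0):
        raise GeometryError(
            f"oocyte outer extent {outer:.1f}px does not fit inside a {s}px image"
        )

    yy, xx = np.mgrid[0:s, 0:s].astype(float)
    X = (xx - cx) * np.cos(theta) + (yy - cy) * np.sin(theta)
    Y = -(xx - cx) * np.sin(theta) + (yy - cy) * np.cos(theta)

    def inside(da: float) -> np.ndarray:
        return (X / (a_c + da)) ** 2 + (Y / (b_c + da)) ** 2 <= 1.0

    cyto = inside(0.0)
    periv = inside(g) & ~cyto
    zona = inside(g + t) & ~inside(g)
    mask = inside(g + t)

    img = np.full((s, s), _BG)
    img[cyto] = _CYTO
    img[periv] = _PERIV
    img[zona] = _ZONA

    if params.texture_amplitude > 0:
        field = ndimage.gaussian_filter(tex_white, params.texture_corr_length,
                                        mode="wrap")
        sd = field.std()
        if sd > 0:
            img[cyto] += params.texture_amplitude * (field[cyto] / sd)
    if params.noise_sd > 0:
        img += params.noise_sd * sens
    np.clip(img, 0.0, 1.0, out=img)
    return SyntheticOocyte(pixels=img, mask=mask, group=group,
                           latent_age=latent_age, source_id=source_id)


def generate_cohort(
    spec: CohortSpec,
    young: MorphologyParams | None = None,
    old: MorphologyParams | None = None,
) -> list[SyntheticOocyte]:
    """Draw the full three-cohort study.

    Treated oocytes flip a latent coin (probability ``p_young_in_treated``) and
    are then rendered from the young or old parameter set accordingly.
    Identical ``spec`` (and params) always reproduce bit-identical pixels.
    """
    spec.validate()
    if young is None or old is None:
        d_young, d_old = default_class_params(spec.effect_size)
        young = young if young is not None else d_young
        old = old if old is not None else d_old
    young.validate()
    old.validate()

    oocytes: list[SyntheticOocyte] = []
    mix_rng = np.random.default_rng(derive_seed(spec.seed, "treated-mixture"))
    for group, n, prefix in (("young", spec.n_young, "Y"),
                             ("old", spec.n_old, "O"),
                             ("treated", spec.n_treated, "T")):
        for i in range(int(n)):
            source_id = f"{prefix}{i + 1:03d}"
            if group == "treated":
                latent = "young-like" if mix_rng.random() < spec.p_young_in_treated \
                    else "old-like"
            else:
                latent = f"{group}-like"
            params = young if latent == "young-like" else old
            rng = np.random.default_rng(derive_seed(spec.seed, "render", source_id))
            oocytes.append(render_oocyte(params, rng, spec.image_side,
                                         group=group, latent_age=latent,
                                         source_id=source_id))
    return oocytes


def write_cohort(oocytes: Sequence[SyntheticOocyte], outdir: str | Path,
                 seed: int = 0) -> Path:
    """Write 16-bit TIFF images, 0/255 PNG masks, and a CSV manifest.

    Returns the manifest path.  Paths inside the manifest are relative to
    ``outdir`` so the directory is relocatable.
    """
    outdir = Path(outdir)
    (outdir / "images").mkdir(parents=True, exist_ok=True)
    (outdir / "masks").mkdir(parents=True, exist_ok=True)
    rows = []
    for oo in oocytes:
        img16 = np.round(np.clip(oo.pixels, 0, 1) * 65535).astype(np.uint16)
        image_path = f"images/{oo.source_id}.tif"
        mask_path = f"masks/{oo.source_id}.png"
        tifffile.imwrite(outdir / image_path, img16)
        iio.imwrite(outdir / mask_path, (oo.mask.astype(np.uint8) * 255))
        rows.append({"image_path": image_path, "mask_path": mask_path,
                     "group": oo.group, "latent_age": oo.latent_age,
                     "source_id": oo.source_id, "seed": seed})
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
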