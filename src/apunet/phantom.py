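"""Synthetic tri-modal phantom generator.

Produces co-registered 50x50 CT / PET / fused PET-CT image triplets with
ground-truth binary lesion masks, emulating the structure of small
lung-lesion ROI crops: a single compact bright lesion, a CT channel with
smooth anatomical-looking texture and weak lesion contrast, a PET channel
with a strong but blurred and noisy hot spot, and the fused channel as a
convex blend of the two. All intensities live in [0, 1].

The generator is deterministic: a (seed, config) pair fixes every pixel.
Lesion-to-background mean-intensity ratios are imposed exactly on the
noise-free images (the additive lesion term is solved for the requested
ratio after blurring/texturing), so the configured contrasts are
verifiable post conditions rather than approximate targets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy import ndimage

__all__ = [
    "ImageTriplet",
    "PhantomConfig",
    "DatasetSplit",
    "generate_mask",
    "render_triplet",
    "generate_triplet",
    "generate_dataset",
]

LESION_SHAPES = ("ellipse", "blob", "lobulated", "mixed")
_EIGHT = np.ones((3, 3), dtype=int)  # 8-connectivity structure


@dataclass
class ImageTriplet:
    """One co-registered sample: CT, PET, fused PET/CT, and lesion mask."""

    ct: np.ndarray
    pet: np.ndarray
    fused: np.ndarray
    mask: np.ndarray
    sample_id: str = ""

    def __post_init__(self):
        shapes = {self.ct.shape, self.pet.shape, self.fused.shape, self.mask.shape}
        if len(shapes) != 1:
            raise ValueError(f"modalities disagree in shape: {shapes}")
        vals = np.unique(self.mask)
        if not np.all(np.isin(vals, [0, 1])):
            raise ValueError("mask must be binary {0,1}")


class PhantomConfig(BaseModel):
    """Knobs of the phantom: geometry, contrast, degradation, fusion.

    ``pet_contrast`` and ``ct_contrast`` are lesion-to-background mean
    intensity ratios on the noise-free images; PET is the high-contrast
    functional channel, CT the low-contrast anatomical one.
    """

    model_config = ConfigDict(extra="forbid")

    image_size: int = Field(50, ge=16)
    lesion_area_range: tuple[float, float] = (0.03, 0.15)
    lesion_shape: Literal[LESION_SHAPES] = "mixed"
    pet_contrast: float = Field(3.0, gt=1.0)
    ct_contrast: float = Field(1.3, gt=1.0)
    noise_sd: float = Field(0.03, ge=0.0)
    pet_blur_sigma: float = Field(1.0, ge=0.0)
    fusion_alpha: float = Field(0.5, ge=0.0, le=1.0)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self):
        lo, hi = self.lesion_area_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError(
                f"lesion_area_range must satisfy 0 < lo <= hi < 1, got {self.lesion_area_range}")
        if self.ct_contrast >= self.pet_contrast:
            raise ValueError("ct_contrast must be below pet_contrast")
        return self


class DatasetSplit(BaseModel):
    """Disjoint train/test sample-id lists."""

    train: list[str]
    test: list[str]

    @model_validator(mode="after")
    def _disjoint(self):
        overlap = set(self.train) & set(self.test)
        if overlap:
            raise ValueError(f"train/test overlap: {sorted(overlap)[:5]}")
        return self


# -----------------------------------------------------------------------------
# Mask generation
# -----------------------------------------------------------------------------

def _grid(size: int):
    return np.meshgrid(np.arange(size), np.arange(size), indexing="ij")


def _ellipse_mask(size: int, area: float, rng: np.random.Generator) -> np.ndarray:
    rr, cc = _grid(size)
    cy, cx = rng.uniform(0.35 * size, 0.65 * size, size=2)
    aspect = rng.uniform(0.5, 1.0)
    theta = rng.uniform(0, np.pi)
    # pi*a*b = area_pixels with b = aspect*a
    a = np.sqrt(area * size * size / (np.pi * aspect))
    b = aspect * a
    dy, dx = rr - cy, cc - cx
    u = dy * np.cos(theta) + dx * np.sin(theta)
    v = -dy * np.sin(theta) + dx * np.cos(theta)
    return ((u / a) ** 2 + (v / b) ** 2 <= 1.0).astype(np.uint8)


def _blob_mask(size: int, area: float, rng: np.random.Generator) -> np.ndarray:
    """Metaball blob: threshold of summed Gaussian bumps at nearby centers."""
    rr, cc = _grid(size)
    k = rng.integers(3, 6)
    cy, cx = rng.uniform(0.4 * size, 0.6 * size, size=2)
    field = np.zeros((size, size))
    base_sigma = np.sqrt(area * size * size / np.pi) * 0.6
    for _ in range(k):
        oy, ox = rng.normal(0, 0.35 * base_sigma + 1.5, size=2)
        sig = base_sigma * rng.uniform(0.6, 1.1)
        field += np.exp(-(((rr - cy - oy) ** 2 + (cc - cx - ox) ** 2)
                          / (2 * sig ** 2)))
    # threshold chosen so the blob hits the target area exactly
    target = int(round(area * size * size))
    thresh = np.partition(field.ravel(), -target)[-target]
    return (field >= thresh).astype(np.uint8)


def _lobulated_mask(size: int, area: float, rng: np.random.Generator) -> np.ndarray:
    """Union of overlapping disks walked from a seed point (lobulated margin)."""
    rr, cc = _grid(size)
    n_lobes = rng.integers(3, 7)
    r0 = np.sqrt(area * size * size / (np.pi * (1 + 0.5 * n_lobes)))
    cy, cx = rng.uniform(0.4 * size, 0.6 * size, size=2)
    mask = np.zeros((size, size), dtype=np.uint8)
    y, x = cy, cx
    for i in range(n_lobes):
        r = r0 * rng.uniform(0.8, 1.3)
        mask |= ((rr - y) ** 2 + (cc - x) ** 2 <= r * r).astype(np.uint8)
        ang = rng.uniform(0, 2 * np.pi)
        step = r * rng.uniform(0.6, 1.0)  # overlap keeps the union connected
        y = np.clip(y + step * np.sin(ang), 0.3 * size, 0.7 * size)
        x = np.clip(x + step * np.cos(ang), 0.3 * size, 0.7 * size)
    return mask


def _is_single_component(mask: np.ndarray) -> bool:
    _, n = ndimage.label(mask, structure=_EIGHT)
    return n == 1


def generate_mask(config: PhantomConfig, rng: np.random.Generator,
                  max_attempts: int = 100) -> np.ndarray:
    """Draw a single 8-connected lesion mask within the configured area range.

    Rejection-samples shape realizations until the rendered area fraction
    lands inside ``lesion_area_range`` and the region is one connected
    component; raises ``RuntimeError`` naming the config after
    ``max_attempts`` failures.
    """
    size = config.image_size
    lo, hi = config.lesion_area_range
    total = size * size
    for _ in range(max_attempts):
        shape = config.lesion_shape
        if shape == "mixed":
            shape = ("ellipse", "blob", "lobulated")[rng.integers(3)]
        area = rng.uniform(lo, hi)
        maker = {"ellipse": _ellipse_mask, "blob": _blob_mask,
                 "lobulated": _lobulated_mask}[shape]
        mask = maker(size, area, rng)
        frac = mask.sum() / total
        if lo <= frac <= hi and _is_single_component(mask):
            return mask
    raise RuntimeError(
        f"could not draw a lesion satisfying area range {config.lesion_area_range} "
        f"with shape {config.lesion_shape!r} at size {size} after {max_attempts} attempts")


# -----------------------------------------------------------------------------
# Rendering
# -----------------------------------------------------------------------------

def _solve_lesion_gain(background: np.ndarray, kernel: np.ndarray,
                       mask: np.ndarray, contrast: float) -> float:
    """Gain c such that mean(bg + c*kernel | in) = contrast * mean(... | out)."""
    inside = mask.astype(bool)
    bg_in = background[inside].mean()
    bg_out = background[~inside].mean()
    k_in = kernel[inside].mean()
    k_out = kernel[~inside].mean()
    denom = k_in - contrast * k_out
    if denom <= 0:
        raise RuntimeError(
            "lesion kernel too diffuse to reach the requested contrast "
            "(reduce pet_blur_sigma or the contrast ratio)")
    return (contrast * bg_out - bg_in) / denom


def render_triplet(mask: np.ndarray, config: PhantomConfig,
                   rng: np.random.Generator, sample_id: str = "") -> ImageTriplet:
    """Render CT / PET / fused images for a given lesion mask.

    The PET channel is a blurred hot spot over a flat background; the CT
    channel is a smooth low-frequency field with mild texture and a weak
    lesion footprint. Mean-intensity contrast ratios are exact on the
    noise-free images; Gaussian pixel noise (sd ``noise_sd``) is then added
    to CT and PET independently and the fused channel is computed as
    ``fusion_alpha * pet + (1 - fusion_alpha) * ct`` from the final images.
    """
    size = config.image_size
    if mask.shape != (size, size):
        raise ValueError(f"mask shape {mask.shape} != config size {size}")
    m = mask.astype(np.float64)

    # PET: flat background + blurred lesion kernel, exact contrast pre-noise
    pet_bg = np.full((size, size), 0.20)
    if config.pet_blur_sigma > 0:
        pet_kernel = ndimage.gaussian_filter(m, config.pet_blur_sigma)
    else:
        pet_kernel = m
    c_pet = _solve_lesion_gain(pet_bg, pet_kernel, mask, config.pet_contrast)
    pet = pet_bg + c_pet * pet_kernel

    # CT: smooth anatomical field + texture + faint lesion footprint
    coarse = rng.normal(size=(size, size))
    field = ndimage.gaussian_filter(coarse, size / 8.0)
    lo_, hi_ = field.min(), field.max()
    span = hi_ - lo_ if hi_ > lo_ else 1.0
    ct_bg = 0.30 + 0.25 * (field - lo_) / span
    ct_bg += 0.02 * ndimage.gaussian_filter(rng.normal(size=(size, size)), 0.8)
    ct_kernel = ndimage.gaussian_filter(m, 0.5) if config.pet_blur_sigma > 0 else m
    c_ct = _solve_lesion_gain(ct_bg, ct_kernel, mask, config.ct_contrast)
    ct = ct_bg + c_ct * ct_kernel

    if config.noise_sd > 0:
        pet = pet + rng.normal(0, config.noise_sd, size=(size, size))
        ct = ct + rng.normal(0, config.noise_sd, size=(size, size))
    pet = np.clip(pet, 0.0, 1.0)
    ct = np.clip(ct, 0.0, 1.0)
    fused = config.fusion_alpha * pet + (1.0 - config.fusion_alpha) * ct
    return ImageTriplet(ct=ct, pet=pet, fused=fused,
                        mask=mask.astype(np.uint8), sample_id=sample_id)


def generate_triplet(config: PhantomConfig, rng: np.random.Generator,
                     sample_id: str = "") -> ImageTriplet:
    """Draw a mask and render its triplet with one RNG stream."""
    mask = generate_mask(config, rng)
    return render_triplet(mask, config, rng, sample_id)


# -----------------------------------------------------------------------------
# Dataset on disk
# -----------------------------------------------------------------------------

def _write_png(path: Path, img: np.ndarray, is_mask: bool = False) -> None:
    from PIL import Image

    if is_mask:
        arr = (img.astype(np.uint8) * 255)
    else:
        arr = np.round(np.clip(img, 0, 1) * 255).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path, format="PNG")


def generate_dataset(n_train: int, n_test: int, config: PhantomConfig,
                     out_dir: str | Path) -> DatasetSplit:
    """Write PNG triplets + masks + a CSV manifest; reproducible from seed.

    Layout: ``<out>/images/<sample_id>_{ct,pet,fused,mask}.png`` and
    ``<out>/manifest.csv`` with columns sample_id, split, ct, pet, fused,
    mask (paths relative to ``out_dir``).
    """
    if n_train <= 0 or n_test <= 0:
        raise ValueError("n_train and n_test must be positive")
    out_dir = Path(out_dir)
    img_dir = out_dir / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    rows = []
    split = DatasetSplit(train=[], test=[])
    for i in range(n_train + n_test):
        part = "train" if i < n_train else "test"
        sid = f"{part}_{i if part == 'train' else i - n_train:04d}"
        triplet = generate_triplet(config, rng, sid)
        paths = {}
        for mod in ("ct", "pet", "fused", "mask"):
            rel = f"images/{sid}_{mod}.png"
            _write_png(out_dir / rel, getattr(triplet, mod), is_mask=(mod == "mask"))
            paths[mod] = rel
        rows.append({"sample_id": sid, "split": part, **paths})
        getattr(split, part).append(sid)
    pd.DataFrame(rows).to_csv(out_dir / "manifest.csv", index=False)
    return split
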