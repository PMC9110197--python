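"""ROI extraction, contrast enhancement, and rigid augmentation.

The preprocessing chain mirrors clinical practice for small pulmonary
lesions: locate the roughly circular lesion with a circular Hough
transform, crop a fixed 50x50 window around it, optionally enhance
contrast, and expand the dataset with lossless 90-degree rotations and
mirror flips.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import exposure, feature, transform

from .phantom import ImageTriplet

__all__ = ["RoiBox", "AugmentSpec", "hough_roi", "crop", "extract_roi",
           "enhance_contrast", "augment"]

ENHANCE_METHODS = ("clahe_like", "gamma", "none")


@dataclass
class RoiBox:
    """A square crop window: center (row, col) and side length in pixels.

    Crops are half-open ``[r0, r0+size) x [c0, c0+size)`` with 0-based
    indices; out-of-bounds regions are filled by edge replication.
    """

    center_row: int
    center_col: int
    size: int


@dataclass
class AugmentSpec:
    """Lossless rigid augmentation: 90-degree rotations and mirror flips."""

    rotations: tuple[int, ...] = (90, 180, 270)
    mirror_horizontal: bool = True
    mirror_vertical: bool = True

    def __post_init__(self):
        bad = [r for r in self.rotations if r not in (90, 180, 270)]
        if bad:
            raise ValueError(f"rotations must be from {{90,180,270}}, got {bad}")


def hough_roi(image: np.ndarray, radius_range: tuple[int, int] = (3, 20),
              out_size: int = 50, accumulator_threshold: float = 0.3,
              canny_sigma: float = 1.5) -> RoiBox:
    """Locate the strongest circular structure and return its crop box.

    Edges (Canny) feed a circular Hough transform over
    ``radius_range = (r_min, r_max)`` inclusive; the global accumulator
    peak fixes the box center. Ties break toward the smaller radius, then
    row-major position. A peak below ``accumulator_threshold`` (normalized
    accumulator votes) raises ``ValueError`` advising a manual ROI.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.shape[0] <= out_size or image.shape[1] <= out_size:
        raise ValueError(
            f"image {image.shape} must exceed out_size {out_size} in both dimensions")
    r_min, r_max = radius_range
    if r_max < r_min:
        raise ValueError(f"empty radius range {radius_range}")
    edges = feature.canny(image, sigma=canny_sigma)
    radii = np.arange(r_min, r_max + 1)
    acc = transform.hough_circle(edges, radii)  # (n_radii, H, W)
    best_val, best = -np.inf, None
    for k in range(len(radii)):  # ascending radius; strict '>' keeps smaller radius on ties
        flat = acc[k].argmax()
        val = acc[k].ravel()[flat]
        if val > best_val:
            best_val = val
            best = np.unravel_index(flat, acc[k].shape)
    if best_val < accumulator_threshold:
        raise ValueError(
            f"no circular Hough peak above threshold {accumulator_threshold} "
            f"(best {best_val:.3f}); select the ROI manually")
    return RoiBox(center_row=int(best[0]), center_col=int(best[1]), size=out_size)


def crop(image: np.ndarray, box: RoiBox) -> np.ndarray:
    """Extract the box, edge-replicating where it exceeds the image."""
    half = box.size // 2
    r0 = box.center_row - half
    c0 = box.center_col - half
    pad_top = max(0, -r0)
    pad_left = max(0, -c0)
    pad_bottom = max(0, r0 + box.size - image.shape[0])
    pad_right = max(0, c0 + box.size - image.shape[1])
    padded = np.pad(image, ((pad_top, pad_bottom), (pad_left, pad_right)),
                    mode="edge")
    r0 += pad_top
    c0 += pad_left
    return padded[r0:r0 + box.size, c0:c0 + box.size]


def extract_roi(image: np.ndarray, radius_range: tuple[int, int] = (3, 20),
                out_size: int = 50, **kwargs) -> tuple[np.ndarray, RoiBox]:
    """Hough-locate then crop; returns (crop, box)."""
    box = hough_roi(image, radius_range, out_size, **kwargs)
    return crop(image, box), box


def enhance_contrast(image: np.ndarray, method: str = "clahe_like",
                     gamma: float = 1.5, clip_limit: float = 0.02) -> np.ndarray:
    """Contrast enhancement on [0,1] images.

    ``none`` is the identity; ``gamma`` applies a power law with exponent
    > 1 (darkens background more than a bright lesion, so the
    lesion/background mean ratio cannot decrease); ``clahe_like`` applies
    contrast-limited adaptive histogram equalization.
    """
    image = np.asarray(image)
    if image.min() < 0 or image.max() > 1:
        raise ValueError("enhance_contrast expects intensities in [0,1]")
    if method == "none":
        return image
    if method == "gamma":
        return np.power(image, gamma)
    if method == "clahe_like":
        if np.ptp(image) == 0:
            return image  # constant image: nothing to equalize
        return exposure.equalize_adapthist(image.astype(np.float64),
                                           clip_limit=clip_limit)
    raise ValueError(f"unknown enhancement method {method!r}; "
                     f"choose from {ENHANCE_METHODS}")


def _transforms(spec: AugmentSpec):
    ops = [("orig", lambda a: a)]
    for rot in spec.rotations:
        k = rot // 90
        ops.append((f"rot{rot}", lambda a, k=k: np.rot90(a, k)))
    if spec.mirror_horizontal:
        ops.append(("fliplr", np.fliplr))
    if spec.mirror_vertical:
        ops.append(("flipud", np.flipud))
    if spec.mirror_horizontal and spec.mirror_vertical:
        # the double mirror (same pixel permutation as a 180-degree
        # rotation) completes the mirror family
        ops.append(("fliplrud", lambda a: np.flipud(np.fliplr(a))))
    return ops


def augment(triplet: ImageTriplet, spec: AugmentSpec | None = None
            ) -> list[ImageTriplet]:
    """Apply the rigid transform set to all four grids of a triplet.

    The original sample is included first; every transform permutes
    pixels, so channel histograms and mask areas are preserved exactly.
    """
    if spec is None:
        spec = AugmentSpec()
    out = []
    for name, op in _transforms(spec):
        sid = triplet.sample_id if name == "orig" else f"{triplet.sample_id}_{name}"
        out.append(ImageTriplet(
            ct=np.ascontiguousarray(op(triplet.ct)),
            pet=np.ascontiguousarray(op(triplet.pet)),
            fused=np.ascontiguousarray(op(triplet.fused)),
            mask=np.ascontiguousarray(op(triplet.mask)),
            sample_id=sid,
        ))
    return out
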