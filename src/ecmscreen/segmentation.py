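"""Texture-based segmentation of a liver-ECM disc in a well scan.

The scaffold shows higher local intensity variance than the bare plate, so
the core of the disc is found with a local standard-deviation filter
followed by a median filter and a threshold. Pixels where the image
deviates strongly from an empty-well light profile are added as
candidates, and a dilation-reconstruction morphological pipeline keeps
candidate structure connected to the textured core, fills holes and trims
noise near the borders. A parameter sweep scores each candidate mask by
how well its area and circularity match the known disc geometry (6 mm
diameter) and returns a ranked list so a human can still override the
automatic choice.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage import measure, morphology

from .types import FieldImage, as_array

__all__ = [
    "SegmentationParams",
    "DiscMask",
    "local_std_filter",
    "candidate_pixels",
    "morph_refine",
    "segment_disc",
    "sweep_segmentation",
    "mask_iou",
]


@dataclass
class SegmentationParams:
    """The swept segmentation parameters.

    std_kernel / median_kernel
        odd window sizes (px) of the local-SD and median filters.
    texture_threshold
        threshold on the filtered texture response defining core pixels.
    candidate_threshold
        absolute intensity deviation from the light profile (image units)
        above which a pixel becomes an on-disc candidate.
    struct_size
        radius (px) of the disk structuring element used by the
        morphological refinement.
    illumination_corrected
        run the texture filter on image - profile instead of the raw
        image; default is the raw image.
    """

    std_kernel: int = 5
    median_kernel: int = 3
    candidate_threshold: float = 120.0
    struct_size: int = 7
    texture_threshold: float = 60.0
    illumination_corrected: bool = False

    def __post_init__(self) -> None:
        for name in ("std_kernel", "median_kernel"):
            k = getattr(self, name)
            if k < 3 or k % 2 == 0:
                raise ValueError(f"{name} must be odd and >= 3, got {k}")
        if self.struct_size < 1:
            raise ValueError("struct_size must be >= 1")
        if self.candidate_threshold <= 0 or self.texture_threshold <= 0:
            raise ValueError("thresholds must be > 0")


@dataclass
class DiscMask:
    """A binary on-disc region plus the parameters and score that made it."""

    mask: np.ndarray
    params: SegmentationParams | None = None
    no_disc: bool = False
    score: float | None = None

    @property
    def area(self) -> int:
        return int(self.mask.sum())

    def circularity(self) -> float:
        """4*pi*area / perimeter^2, clipped to [0, 1] (1 = perfect circle)."""
        if self.no_disc or self.area == 0:
            return 0.0
        perim = measure.perimeter_crofton(self.mask, directions=4)
        if perim == 0:
            return 0.0
        return float(min(4.0 * np.pi * self.area / perim**2, 1.0))


def local_std_filter(image: FieldImage | np.ndarray, kernel: int) -> np.ndarray:
    """Local population standard deviation in a kernel x kernel window.

    Border handling is reflection. Population (divide-by-n) SD is the
    convention of standard image STD filters; after thresholding the
    n vs n-1 choice is immaterial.
    """
    arr = as_array(image)
    if kernel % 2 == 0:
        raise ValueError(f"kernel must be odd, got {kernel}")
    if kernel > min(arr.shape):
        raise ValueError("kernel exceeds image dimensions")
    mean = ndimage.uniform_filter(arr, size=kernel, mode="reflect")
    mean_sq = ndimage.uniform_filter(arr * arr, size=kernel, mode="reflect")
    var = np.clip(mean_sq - mean * mean, 0.0, None)
    return np.sqrt(var)


def candidate_pixels(
    image: FieldImage | np.ndarray, profile: FieldImage | np.ndarray, threshold: float
) -> np.ndarray:
    """Pixels whose deviation from the empty-well light profile exceeds threshold."""
    a, b = as_array(image), as_array(profile)
    if a.shape != b.shape:
        raise ValueError(f"image shape {a.shape} != profile shape {b.shape}")
    return np.abs(a - b) > threshold


def morph_refine(core: np.ndarray, candidates: np.ndarray, struct_size: int) -> DiscMask:
    """Refine the textured core with candidates via dilation-reconstruction.

    Pipeline: union core|candidates -> dilate by disk(struct_size) ->
    morphological reconstruction from the core (keeping only structure
    connected to core pixels) -> hole filling -> erosion by the same disk
    (undoing the dilation bias) -> largest connected component.

    An empty core yields an empty mask flagged ``no_disc`` rather than an
    exception.
    """
    core = np.asarray(core, bool)
    candidates = np.asarray(candidates, bool)
    if core.shape != candidates.shape:
        raise ValueError("core and candidates must have the same shape")
    if not core.any():
        return DiscMask(np.zeros_like(core), no_disc=True)
    footprint = morphology.disk(struct_size)
    dilated = morphology.dilation(core | candidates, footprint)
    recon = morphology.reconstruction(
        core.astype(np.uint8), dilated.astype(np.uint8), method="dilation"
    ).astype(bool)
    filled = ndimage.binary_fill_holes(recon)
    eroded = morphology.erosion(filled, footprint)
    if not eroded.any():
        return DiscMask(np.zeros_like(core), no_disc=True)
    labels = measure.label(eroded, connectivity=2)
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    return DiscMask(labels == largest)


def segment_disc(
    image: FieldImage | np.ndarray,
    profile: FieldImage | np.ndarray,
    params: SegmentationParams | None = None,
) -> DiscMask:
    """Full disc segmentation: texture core + light-profile candidates + refinement."""
    params = params or SegmentationParams()
    arr = as_array(image)
    prof = as_array(profile)
    tex_input = arr - prof if params.illumination_corrected else arr
    response = ndimage.median_filter(
        local_std_filter(tex_input, params.std_kernel), size=params.median_kernel, mode="reflect"
    )
    core = response > params.texture_threshold
    cand = candidate_pixels(arr, prof, params.candidate_threshold)
    result = morph_refine(core, cand, params.struct_size)
    result.params = params
    return result


def _score(mask: DiscMask, expected_area: float, circularity_weight: float) -> float:
    if mask.no_disc or mask.area == 0:
        return float("inf")
    area_term = abs(mask.area - expected_area) / expected_area
    return area_term + circularity_weight * (1.0 - mask.circularity())


def sweep_segmentation(
    image: FieldImage | np.ndarray,
    profile: FieldImage | np.ndarray,
    grid: Sequence[SegmentationParams],
    expected_area: float,
    circularity_weight: float = 1.0,
) -> tuple[DiscMask, list[DiscMask]]:
    """Run the segmentation over a parameter grid and pick the best mask.

    Each candidate is scored S = |area - expected_area|/expected_area +
    circularity_weight*(1 - circularity); the lowest S wins, ties broken
    by earlier grid position. The full ranking is returned so the
    automatic choice can be overridden manually.
    """
    if not grid:
        raise ValueError("parameter grid must be non-empty")
    if expected_area <= 0:
        raise ValueError("expected_area must be > 0")
    masks: list[DiscMask] = []
    for params in grid:
        m = segment_disc(image, profile, params)
        m.score = _score(m, expected_area, circularity_weight)
        masks.append(m)
    order = sorted(range(len(masks)), key=lambda i: (masks[i].score, i))
    ranked = [masks[i] for i in order]
    best = ranked[0]
    if not np.isfinite(best.score):
        return DiscMask(np.zeros_like(best.mask), no_disc=True, score=float("inf")), ranked
    return best, ranked


def mask_iou(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection over union of two binary masks."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)
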