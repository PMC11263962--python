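"""Contamination mask construction.

High-contrast features — gold fiducials, ice contamination, hot pixels,
reconstruction artifacts — confound a density-minimum picker. The mask marks
them (1 = contamination, 0 = pickable) with a sequence of:

1. background subtraction (wide Gaussian, see :mod:`tomopick.preprocess`);
2. robust thresholding at ``k`` standard deviations from the volume mean, using
   intrinsic image statistics so the same ``k`` transfers across tomograms;
3. regularization: small-component cleaning, binary closing, dilation.

The threshold is two-sided by default (``|v - mean| > k*std``): dense gold and
thick ice are dark under the same convention that makes particles dark, while
Fresnel fringes flanking them are bright. ``two_sided=False`` keeps only the
dark tail.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import ball

from .io import Tomogram
from .preprocess import DEFAULT_BACKGROUND_SIGMA_ANGSTROM, subtract_background

__all__ = [
    "MaskParams",
    "threshold_volume",
    "remove_small_components",
    "close_mask",
    "dilate_mask",
    "build_contamination_mask",
]

logger = logging.getLogger(__name__)

# 26-connectivity: diagonal-touching voxels belong to one component
_CONNECTIVITY = np.ones((3, 3, 3), dtype=bool)


@dataclass
class MaskParams:
    """Contamination-mask parameters.

    ``threshold_k`` is in multiples of the volume gray-value standard
    deviation; ``min_component_voxels`` is a voxel count (the 125 default is a
    5x5x5 speck); ``dilation_angstrom`` is converted to voxels by pixel size.
    """

    threshold_k: float = 2.0
    min_component_voxels: int = 125
    closing_radius_voxels: int = 2
    dilation_angstrom: float = 70.0
    background_sigma_angstrom: float = DEFAULT_BACKGROUND_SIGMA_ANGSTROM
    two_sided: bool = True

    def __post_init__(self) -> None:
        if self.min_component_voxels < 1:
            raise ValueError("min_component_voxels must be >= 1")
        if self.dilation_angstrom < 0 or self.closing_radius_voxels < 0:
            raise ValueError("dilation and closing radii must be >= 0")
        if self.background_sigma_angstrom <= 0:
            raise ValueError("background_sigma_angstrom must be > 0")


def threshold_volume(tomo: Tomogram, k: float, two_sided: bool = True) -> np.ndarray:
    """Threshold at ``k`` standard deviations from the volume mean.

    Two-sided: voxel is 1 iff ``|v - mean| > k*std``. One-sided keeps the dark
    tail only (``v < mean - k*std``). A constant volume yields an empty mask
    with a warning.
    """
    vol = tomo.voxels
    mean = float(vol.mean())
    std = float(vol.std())
    if std == 0.0:
        logger.warning("threshold_volume: constant volume (std=0), empty mask")
        return np.zeros(vol.shape, dtype=bool)
    if two_sided:
        return np.abs(vol - mean) > k * std
    return vol < mean - k * std


def remove_small_components(mask: np.ndarray, min_voxels: int) -> np.ndarray:
    """Drop 26-connected components smaller than ``min_voxels`` (>= kept)."""
    mask = np.asarray(mask, dtype=bool)
    if min_voxels <= 1 or not mask.any():
        return mask.copy()
    labels, n = ndimage.label(mask, structure=_CONNECTIVITY)
    if n == 0:
        return mask.copy()
    sizes = np.bincount(labels.ravel())
    keep = sizes >= min_voxels
    keep[0] = False
    return keep[labels]


def close_mask(mask: np.ndarray, radius_voxels: int) -> np.ndarray:
    """Morphological closing with a Euclidean ball; extensive and idempotent.

    The mask is padded by the ball radius before closing so the dilation is
    not clipped at the volume faces (unpadded closing erodes border voxels,
    breaking extensivity).
    """
    mask = np.asarray(mask, dtype=bool)
    if radius_voxels == 0 or not mask.any():
        return mask.copy()
    selem = ball(radius_voxels)
    padded = np.pad(mask, radius_voxels, mode="constant", constant_values=False)
    closed = ndimage.binary_closing(padded, structure=selem)
    r = radius_voxels
    return closed[r:-r, r:-r, r:-r]


def dilate_mask(mask: np.ndarray, dilation_angstrom: float, pixel_size: float) -> np.ndarray:
    """Dilate by a ball of radius ``round(dilation_angstrom / pixel_size)`` voxels."""
    if pixel_size <= 0:
        raise ValueError(f"pixel_size must be > 0, got {pixel_size}")
    mask = np.asarray(mask, dtype=bool)
    radius = int(round(dilation_angstrom / pixel_size))
    if radius == 0 or not mask.any():
        return mask.copy()
    return ndimage.binary_dilation(mask, structure=ball(radius))


def build_contamination_mask(tomo: Tomogram, params: MaskParams) -> np.ndarray:
    """Full mask pipeline: subtract background, threshold, clean, close, dilate."""
    flat = subtract_background(tomo, params.background_sigma_angstrom)
    mask = threshold_volume(flat, params.threshold_k, two_sided=params.two_sided)
    logger.info("mask: %d voxels above threshold", int(mask.sum()))
    mask = remove_small_components(mask, params.min_component_voxels)
    logger.info("mask: %d voxels after cleaning", int(mask.sum()))
    mask = close_mask(mask, params.closing_radius_voxels)
    logger.info("mask: %d voxels after closing", int(mask.sum()))
    mask = dilate_mask(mask, params.dilation_angstrom, tomo.pixel_size)
    logger.info("mask: %d voxels after dilation", int(mask.sum()))
    return mask
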