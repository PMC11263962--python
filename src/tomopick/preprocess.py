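"""Gaussian filtering utilities.

Two distinct smoothing roles:

* :func:`subtract_background` — remove low-frequency contrast variations
  (ice-thickness gradients, uneven illumination) before mask thresholding, by
  subtracting a wide Gaussian blur (sigma given in Å, default 200).
* :func:`lowpass_for_detection` — suppress sub-particle-scale noise before
  local-minimum detection, with sigma tied to the particle radius
  (``sigma = sigma_factor * r`` voxels, default factor 0.5).

Boundaries are handled by nearest-edge replication so volume faces do not
acquire dark wrap-around artifacts that would read as spurious minima.
Particles are assumed darker than the surrounding density; use
:func:`invert_contrast` for reconstructions with the opposite convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import Tomogram

__all__ = [
    "FilterParams",
    "gaussian_smooth",
    "subtract_background",
    "lowpass_for_detection",
    "invert_contrast",
    "DEFAULT_BACKGROUND_SIGMA_ANGSTROM",
    "DEFAULT_LOWPASS_SIGMA_FACTOR",
]

logger = logging.getLogger(__name__)

DEFAULT_BACKGROUND_SIGMA_ANGSTROM = 200.0
DEFAULT_LOWPASS_SIGMA_FACTOR = 0.5


@dataclass
class FilterParams:
    background_sigma_angstrom: float = DEFAULT_BACKGROUND_SIGMA_ANGSTROM
    lowpass_sigma_factor: float = DEFAULT_LOWPASS_SIGMA_FACTOR

    def __post_init__(self) -> None:
        if self.background_sigma_angstrom <= 0 or self.lowpass_sigma_factor <= 0:
            raise ValueError("filter sigmas must be > 0")


def gaussian_smooth(tomo: Tomogram, sigma_voxels: float) -> Tomogram:
    """Isotropic 3D Gaussian smoothing with replicate-edge boundaries."""
    if sigma_voxels <= 0:
        raise ValueError(f"sigma_voxels must be > 0, got {sigma_voxels}")
    if 2 * sigma_voxels > min(tomo.voxels.shape):
        logger.warning(
            "Gaussian sigma %.3g exceeds half the smallest volume dimension %d",
            sigma_voxels, min(tomo.voxels.shape),
        )
    out = ndimage.gaussian_filter(
        tomo.voxels.astype(np.float32, copy=False), sigma=sigma_voxels, mode="nearest"
    )
    return Tomogram(out, tomo.pixel_size, tomo.origin)


def subtract_background(
    tomo: Tomogram, sigma_angstrom: float = DEFAULT_BACKGROUND_SIGMA_ANGSTROM
) -> Tomogram:
    """Remove low-frequency background: ``tomo - smooth(tomo, sigma/pixel_size)``."""
    if sigma_angstrom <= 0:
        raise ValueError(f"sigma_angstrom must be > 0, got {sigma_angstrom}")
    sigma_voxels = sigma_angstrom / tomo.pixel_size
    smooth = gaussian_smooth(tomo, sigma_voxels)
    return Tomogram(tomo.voxels - smooth.voxels, tomo.pixel_size, tomo.origin)


def lowpass_for_detection(
    tomo: Tomogram,
    radius_voxels: int,
    sigma_factor: float = DEFAULT_LOWPASS_SIGMA_FACTOR,
) -> Tomogram:
    """Low-pass at the particle scale: Gaussian with sigma = sigma_factor * r."""
    if radius_voxels < 1:
        raise ValueError(f"radius_voxels must be >= 1, got {radius_voxels}")
    if sigma_factor <= 0:
        raise ValueError(f"sigma_factor must be > 0, got {sigma_factor}")
    return gaussian_smooth(tomo, sigma_factor * radius_voxels)


def invert_contrast(tomo: Tomogram) -> Tomogram:
    """Negate the volume (for reconstructions where particles are bright)."""
    return Tomogram(-tomo.voxels, tomo.pixel_size, tomo.origin)
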