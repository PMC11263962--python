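"""Candidate detection: local density minima at the particle scale.

Candidates are voxels strictly darker than every other voxel in a centered
cubic window. Two window regimes, both derived from the particle radius ``r``
(voxels):

* ``4r`` mode — window side ``4r + 1``. Disjoint strict-minimum windows
  guarantee non-overlapping particles, but a stray dark voxel within ``2r`` of
  a true center suppresses it (false negatives).
* ``2r`` mode (default) — window side ``2r + 1``, followed by greedy
  darkest-first suppression that discards any candidate closer than ``2r``
  (Euclidean) to an already-kept one. Recovers centers the wide window misses
  while still enforcing the minimum center separation of ``2r``.

Since ``h = 4r`` and ``h = 2r`` are even, the centered window uses the odd
side ``2*(h//2) + 1``; the guarantee radius is ``h//2``. Ties (plateaus) yield
no candidate at either voxel: strictness keeps the definition unambiguous.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import Tomogram
from .particles import (
    Candidate,
    STATUS_CANDIDATE,
    STATUS_REJECTED_BOUNDARY,
    STATUS_REJECTED_MASK,
    STATUS_REJECTED_SLAB,
)

__all__ = [
    "DetectParams",
    "find_local_minima",
    "detect_candidates_4r",
    "detect_candidates_2r",
    "suppress_close_candidates",
    "reject_boundary",
    "exclude_masked",
    "restrict_slab",
    "filter_subvolume_side",
]

logger = logging.getLogger(__name__)


@dataclass
class DetectParams:
    """Detection parameters (radius in Å; mode ``"2r"`` or ``"4r"``).

    ``detection_width_slices`` restricts candidates to a band of z-slices
    around the tomogram mid-plane; the default covers any volume (picks from
    all slices), thin-ice samples use a narrow band such as 32.
    """

    radius_angstrom: float = 100.0
    mode: str = "2r"
    detection_width_slices: int = 10**6
    lowpass_sigma_factor: float = 0.5

    def __post_init__(self) -> None:
        if self.radius_angstrom <= 0:
            raise ValueError("radius_angstrom must be > 0")
        if self.mode not in ("2r", "4r"):
            raise ValueError(f"mode must be '2r' or '4r', got {self.mode!r}")
        if self.detection_width_slices < 1:
            raise ValueError("detection_width_slices must be >= 1")


def filter_subvolume_side(radius_voxels: int) -> int:
    """Side of the (3r)^3 filtering subvolume, rounded up to odd."""
    side = 3 * radius_voxels
    return side if side % 2 == 1 else side + 1


def find_local_minima(tomo: Tomogram, h: int) -> list[Candidate]:
    """Strict local minima in centered cubic windows of side ``2*(h//2)+1``.

    A voxel qualifies iff its value is strictly smaller than every other voxel
    in the window (clipped at volume faces). Returned in array scan order
    (z, then y, then x); positions are (x, y, z).
    """
    if h < 3:
        raise ValueError(f"h must be >= 3, got {h}")
    side = 2 * (h // 2) + 1
    vol = tomo.voxels
    if side > min(vol.shape):
        logger.warning(
            "minimum window side %d exceeds smallest volume dimension %d; "
            "result reduces to the global minimum (if unique)", side, min(vol.shape),
        )
    footprint = np.ones((side, side, side), dtype=bool)
    footprint[side // 2, side // 2, side // 2] = False
    # min over the window excluding the center; +inf outside the volume
    neighbor_min = ndimage.minimum_filter(
        vol, footprint=footprint, mode="constant", cval=np.inf
    )
    is_min = vol < neighbor_min
    out: list[Candidate] = []
    for z, y, x in np.argwhere(is_min):
        out.append(Candidate(position=(int(x), int(y), int(z)), density=float(vol[z, y, x])))
    return out


def _sort_by_density(cands: list[Candidate]) -> list[Candidate]:
    return sorted(cands, key=lambda c: (c.density, c.position))


def suppress_close_candidates(
    candidates: list[Candidate], min_distance: float
) -> list[Candidate]:
    """Greedy darkest-first suppression at Euclidean ``min_distance``.

    Candidates are visited in ascending density (ties broken by position); a
    candidate is kept iff its distance to every already-kept candidate is
    >= ``min_distance`` (strict-< rejection, so two points at exactly the
    minimum distance are both kept).
    """
    kept: list[Candidate] = []
    kept_xyz: list[np.ndarray] = []
    min_sq = float(min_distance) ** 2
    for cand in _sort_by_density(candidates):
        p = np.asarray(cand.position, dtype=float)
        if all(((p - q) ** 2).sum() >= min_sq for q in kept_xyz):
            kept.append(cand)
            kept_xyz.append(p)
    return kept


def reject_boundary(
    candidates: list[Candidate], shape_zyx: tuple[int, int, int], margin: int
) -> list[Candidate]:
    """Mark candidates within ``margin`` voxels of any volume face.

    Such positions cannot host the full (3r)^3 filtering subvolume, so their
    projection statistics would not be comparable; they get status
    ``rejected_boundary``. Order preserved.
    """
    nz, ny, nx = shape_zyx
    out: list[Candidate] = []
    n_rej = 0
    for cand in candidates:
        x, y, z = cand.position
        inside = (
            margin <= x < nx - margin
            and margin <= y < ny - margin
            and margin <= z < nz - margin
        )
        if inside:
            out.append(cand)
        else:
            out.append(cand.with_status(STATUS_REJECTED_BOUNDARY, "truncated subvolume"))
            n_rej += 1
    if n_rej:
        logger.info("rejected %d candidates within %d voxels of a volume face", n_rej, margin)
    return out


def detect_candidates_4r(tomo: Tomogram, params: DetectParams) -> list[Candidate]:
    """Local minima in windows of side ``4r + 1``, darkest first."""
    r = tomo.radius_voxels(params.radius_angstrom)
    minima = find_local_minima(tomo, 4 * r)
    return _sort_by_density(minima)


def detect_candidates_2r(tomo: Tomogram, params: DetectParams) -> list[Candidate]:
    """Local minima in windows of side ``2r + 1`` plus greedy 2r suppression."""
    r = tomo.radius_voxels(params.radius_angstrom)
    minima = find_local_minima(tomo, 2 * r)
    return suppress_close_candidates(minima, 2.0 * r)


def exclude_masked(candidates: list[Candidate], mask: np.ndarray) -> list[Candidate]:
    """Mark candidates whose position lies inside the contamination mask."""
    mask = np.asarray(mask, dtype=bool)
    out: list[Candidate] = []
    for cand in candidates:
        if cand.status != STATUS_CANDIDATE:
            out.append(cand)
            continue
        z, y, x = cand.zyx
        if not (0 <= z < mask.shape[0] and 0 <= y < mask.shape[1] and 0 <= x < mask.shape[2]):
            raise ValueError(f"candidate {cand.position} outside mask of shape {mask.shape}")
        out.append(cand.with_status(STATUS_REJECTED_MASK) if mask[z, y, x] else cand)
    return out


def restrict_slab(candidates: list[Candidate], width_slices: int, nz: int) -> list[Candidate]:
    """Keep candidates within ``width_slices/2`` of the mid-plane ``nz/2``.

    The default width in :class:`DetectParams` exceeds any volume, so all
    slices are kept unless a narrow band is requested (thin-ice samples).
    """
    if width_slices < 1:
        raise ValueError("width_slices must be >= 1")
    mid = nz / 2.0
    half = width_slices / 2.0
    out: list[Candidate] = []
    for cand in candidates:
        if cand.status != STATUS_CANDIDATE:
            out.append(cand)
            continue
        z = cand.position[2]
        out.append(cand if abs(z - mid) <= half else cand.with_status(STATUS_REJECTED_SLAB))
    return out
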