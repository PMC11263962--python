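"""Candidate filtering by local projection statistics.

For each surviving candidate a ``(3r)^3`` subvolume is extracted, averaged
along z into a 2D projection, and split into a *foreground* (central circle of
radius ``r``) and *background* (its complement). Two criteria decide
acceptance:

* threshold — ``fg_std > proj_mean + filter_k * proj_std``. The inequality
  compares a dispersion to a location-plus-dispersion threshold; to make it
  behave predictably across datasets the input volume is standardized to a
  global z-score first, so ``proj_mean`` is near zero for featureless regions
  and the rule degrades gracefully to ``fg_std > filter_k * proj_std``.
  ``filter_k`` may be negative ("accept everything by threshold, rely on the
  other criteria").
* background — accept only if ``bg_std < fg_std``. Intended for crowded
  (in-situ) volumes: a candidate flanked by a membrane or other high-contrast
  object has a noisy background and is discarded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .detect import filter_subvolume_side
from .io import Tomogram
from .particles import (
    Candidate,
    ParticleSet,
    STATUS_ACCEPTED,
    STATUS_CANDIDATE,
    STATUS_REJECTED_STAT,
)

__all__ = [
    "FilterCriteria",
    "ProjectionStats",
    "extract_projection",
    "projection_stats",
    "accept_candidate",
    "filter_particles",
    "standardize",
]

logger = logging.getLogger(__name__)


@dataclass
class FilterCriteria:
    filter_k: float = 1.0
    use_background_criterion: bool = True


@dataclass
class ProjectionStats:
    """Statistics of one candidate's Z-projection (population std, ddof=0)."""

    fg_std: float
    bg_std: float
    proj_mean: float
    proj_std: float


def standardize(tomo: Tomogram) -> Tomogram:
    """Global z-score of the volume (mean 0, std 1)."""
    vol = tomo.voxels
    std = float(vol.std())
    if std == 0.0:
        logger.warning("standardize: constant volume, returning zeros")
        return Tomogram(np.zeros_like(vol, dtype=np.float32), tomo.pixel_size, tomo.origin)
    out = (vol - float(vol.mean())) / std
    return Tomogram(out.astype(np.float32), tomo.pixel_size, tomo.origin)


def extract_projection(
    tomo: Tomogram, center: tuple[int, int, int], r_voxels: int
) -> np.ndarray:
    """Mean-along-z projection of the (3r)^3 subvolume centered at ``center``.

    ``center`` is (x, y, z); the subvolume side is 3r rounded up to odd so the
    candidate voxel is the exact center. Raises if the subvolume would cross a
    volume face (upstream boundary rejection prevents this in the pipeline).
    """
    side = filter_subvolume_side(r_voxels)
    half = side // 2
    x, y, z = center
    nz, ny, nx = tomo.voxels.shape
    if not (half <= x < nx - half and half <= y < ny - half and half <= z < nz - half):
        raise ValueError(
            f"subvolume of side {side} at {center} crosses a face of volume "
            f"(nx,ny,nz)=({nx},{ny},{nz})"
        )
    sub = tomo.voxels[z - half : z + half + 1, y - half : y + half + 1, x - half : x + half + 1]
    return sub.mean(axis=0)


def _foreground_disc(side: int, r_voxels: int) -> np.ndarray:
    c = side // 2
    yy, xx = np.mgrid[0:side, 0:side]
    return (yy - c) ** 2 + (xx - c) ** 2 <= r_voxels**2


def projection_stats(proj: np.ndarray, r_voxels: int) -> ProjectionStats:
    """Foreground/background/global statistics of a projection image.

    Foreground = pixels within ``r`` of the image center; background = the
    rest. The two regions partition the image exactly.
    """
    proj = np.asarray(proj)
    side = proj.shape[0]
    if proj.shape != (side, side):
        raise ValueError(f"projection must be square, got {proj.shape}")
    fg = _foreground_disc(side, r_voxels)
    return ProjectionStats(
        fg_std=float(proj[fg].std()),
        bg_std=float(proj[~fg].std()) if (~fg).any() else 0.0,
        proj_mean=float(proj.mean()),
        proj_std=float(proj.std()),
    )


def accept_candidate(stats: ProjectionStats, criteria: FilterCriteria) -> tuple[bool, str]:
    """Apply the threshold and (optionally) background criteria.

    Returns ``(accepted, reason)`` where reason is ``"accepted"``,
    ``"threshold"`` or ``"background"``.
    """
    threshold = stats.proj_mean + criteria.filter_k * stats.proj_std
    if not stats.fg_std > threshold:
        return False, "threshold"
    if criteria.use_background_criterion and not stats.bg_std < stats.fg_std:
        return False, "background"
    return True, "accepted"


def filter_particles(
    tomo: Tomogram,
    candidates: list[Candidate],
    r_voxels: int,
    criteria: FilterCriteria,
    radius_angstrom: float | None = None,
) -> ParticleSet:
    """Score and accept/reject every live candidate.

    ``tomo`` should be the background-subtracted volume; it is standardized
    here before statistics are computed. Candidates already rejected upstream
    pass through with their status; live candidates end as ``accepted`` or
    ``rejected_stat`` with ``fg_std``/``bg_std`` filled in.
    """
    vol = standardize(tomo)
    out: list[Candidate] = []
    for cand in candidates:
        if cand.status != STATUS_CANDIDATE:
            out.append(cand)
            continue
        proj = extract_projection(vol, cand.position, r_voxels)
        stats = projection_stats(proj, r_voxels)
        cand.fg_std = stats.fg_std
        cand.bg_std = stats.bg_std
        ok, reason = accept_candidate(stats, criteria)
        out.append(
            cand.with_status(STATUS_ACCEPTED)
            if ok
            else cand.with_status(STATUS_REJECTED_STAT, reason)
        )
    pset = ParticleSet(
        candidates=out,
        radius_voxels=r_voxels,
        radius_angstrom=(
            radius_angstrom if radius_angstrom is not None else r_voxels * tomo.pixel_size
        ),
        provenance={
            "filter_k": criteria.filter_k,
            "use_background_criterion": criteria.use_background_criterion,
        },
    )
    logger.info("filtering: %s", pset.count_by_status())
    return pset
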