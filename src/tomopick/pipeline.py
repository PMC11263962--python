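"""End-to-end picking pipeline.

``run_picking`` executes the full workflow on one tomogram:

    subtract_background -> contamination mask -> low-pass ->
    local-minimum detection (2r or 4r mode) -> mask exclusion ->
    slab restriction -> projection-statistics filtering

and finishes with a post-hoc validator asserting the output contract: every
accepted particle lies outside the mask, inside the slab, respects the
mode's minimum separation, and passes the filter criteria. ``run_batch``
applies it over a list of tomograms, surviving per-tomogram failures.

The picker is deterministic: identical input and configuration produce
byte-identical coordinate files.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import detect as _detect
from .filtering import FilterCriteria, filter_particles
from .io import Tomogram, read_tomogram, write_coordinates, write_mask
from .mask import MaskParams, build_contamination_mask
from .particles import ParticleSet, STATUS_ACCEPTED, STATUS_CANDIDATE
from .preprocess import (
    DEFAULT_BACKGROUND_SIGMA_ANGSTROM,
    invert_contrast,
    lowpass_for_detection,
    subtract_background,
)

__all__ = ["PickingConfig", "PickResult", "run_picking", "run_batch", "validate_result"]

logger = logging.getLogger(__name__)


@dataclass
class PickingConfig:
    """Serializable bundle of every pipeline parameter."""

    pixel_size: float | None = None  # Å; None = trust the MRC header
    radius_angstrom: float = 100.0
    mode: str = "2r"
    invert: bool = False
    lowpass_sigma_factor: float = 0.5
    background_sigma_angstrom: float = DEFAULT_BACKGROUND_SIGMA_ANGSTROM
    mask_threshold_k: float = 2.0
    mask_min_component_voxels: int = 125
    mask_closing_radius_voxels: int = 2
    mask_dilation_angstrom: float = 70.0
    mask_two_sided: bool = True
    detection_width_slices: int = 10**6
    filter_k: float = 1.0
    use_background_criterion: bool = True
    coordinate_format: str = "tsv"
    coordinate_scale: float = 1.0

    def copy(self) -> "PickingConfig":
        return dataclasses.replace(self)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PickingConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PickingConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def mask_params(self) -> MaskParams:
        return MaskParams(
            threshold_k=self.mask_threshold_k,
            min_component_voxels=self.mask_min_component_voxels,
            closing_radius_voxels=self.mask_closing_radius_voxels,
            dilation_angstrom=self.mask_dilation_angstrom,
            background_sigma_angstrom=self.background_sigma_angstrom,
            two_sided=self.mask_two_sided,
        )

    def detect_params(self) -> _detect.DetectParams:
        return _detect.DetectParams(
            radius_angstrom=self.radius_angstrom,
            mode=self.mode,
            detection_width_slices=self.detection_width_slices,
            lowpass_sigma_factor=self.lowpass_sigma_factor,
        )

    def filter_criteria(self) -> FilterCriteria:
        return FilterCriteria(
            filter_k=self.filter_k,
            use_background_criterion=self.use_background_criterion,
        )


@dataclass
class PickResult:
    particles: ParticleSet
    mask: np.ndarray
    stage_counts: dict[str, int] = field(default_factory=dict)
    wall_time_s: float = 0.0


def run_picking(
    tomo: Tomogram | str | Path,
    config: PickingConfig,
    out_coords: str | Path | None = None,
    out_mask: str | Path | None = None,
    out_stats: str | Path | None = None,
    out_config: str | Path | None = None,
) -> PickResult:
    """Pick particles from one tomogram; optionally write artifacts."""
    t0 = time.perf_counter()
    if not isinstance(tomo, Tomogram):
        tomo = read_tomogram(tomo, pixel_size=config.pixel_size)
    elif config.pixel_size is not None and tomo.pixel_size != config.pixel_size:
        tomo = Tomogram(tomo.voxels, config.pixel_size, tomo.origin)
    if config.invert:
        tomo = invert_contrast(tomo)
    r = tomo.radius_voxels(config.radius_angstrom)
    counts: dict[str, int] = {}

    flat = subtract_background(tomo, config.background_sigma_angstrom)
    mask = build_contamination_mask(tomo, config.mask_params())
    counts["mask_voxels"] = int(mask.sum())

    lowpassed = lowpass_for_detection(tomo, r, config.lowpass_sigma_factor)
    dp = config.detect_params()
    if config.mode == "4r":
        cands = _detect.detect_candidates_4r(lowpassed, dp)
    else:
        cands = _detect.detect_candidates_2r(lowpassed, dp)
    counts["minima"] = len(cands)

    margin = _detect.filter_subvolume_side(r) // 2
    cands = _detect.reject_boundary(cands, tomo.voxels.shape, margin)
    cands = _detect.exclude_masked(cands, mask)
    cands = _detect.restrict_slab(cands, config.detection_width_slices, tomo.voxels.shape[0])
    counts["after_mask_slab"] = sum(c.status == STATUS_CANDIDATE for c in cands)

    particles = filter_particles(
        flat, cands, r, config.filter_criteria(), radius_angstrom=config.radius_angstrom
    )
    particles.provenance["config"] = config.to_dict()
    counts["accepted"] = len(particles.accepted)
    logger.info(
        "picking: %d minima -> %d after mask/slab -> %d accepted",
        counts["minima"], counts["after_mask_slab"], counts["accepted"],
    )

    validate_result(particles, mask, config, tomo.voxels.shape, r)

    if out_coords is not None:
        write_coordinates(particles, out_coords, format=config.coordinate_format,
                          scale=config.coordinate_scale)
    if out_mask is not None:
        write_mask(mask, tomo.pixel_size, out_mask)
    if out_stats is not None:
        _write_stats(particles, out_stats)
    if out_config is not None:
        config.to_yaml(out_config)
    return PickResult(particles, mask, counts, time.perf_counter() - t0)


def _write_stats(particles: ParticleSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("x\ty\tz\tdensity\tfg_std\tbg_std\tstatus\treason\n")
        for c in particles:
            fg = "" if c.fg_std is None else f"{c.fg_std:.6g}"
            bg = "" if c.bg_std is None else f"{c.bg_std:.6g}"
            x, y, z = c.position
            fh.write(f"{x}\t{y}\t{z}\t{c.density:.6g}\t{fg}\t{bg}\t{c.status}\t{c.reason}\n")


def validate_result(
    particles: ParticleSet,
    mask: np.ndarray,
    config: PickingConfig,
    shape_zyx: tuple[int, int, int],
    r_voxels: int,
) -> None:
    """Assert the output contract on every accepted particle."""
    accepted = particles.accepted
    nz = shape_zyx[0]
    half = config.detection_width_slices / 2.0
    for c in accepted:
        z, y, x = c.zyx
        if mask[z, y, x]:
            raise AssertionError(f"accepted particle {c.position} inside contamination mask")
        if abs(c.position[2] - nz / 2.0) > half:
            raise AssertionError(f"accepted particle {c.position} outside detection slab")
    pos = np.array([c.position for c in accepted], dtype=float)
    if len(pos) >= 2:
        d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=2)
        np.fill_diagonal(d, np.inf)
        if config.mode == "2r":
            if d.min() < 2.0 * r_voxels:
                raise AssertionError("accepted pair closer than 2r (Euclidean)")
        else:
            cheb = np.abs(pos[:, None, :] - pos[None, :, :]).max(axis=2)
            np.fill_diagonal(cheb, np.inf)
            if cheb.min() < 2 * r_voxels + 1:
                raise AssertionError("accepted pair closer than 2r+1 (Chebyshev)")


def run_batch(
    paths: list[str | Path],
    config: PickingConfig,
    out_dir: str | Path,
) -> list[dict[str, Any]]:
    """Run the pipeline over several tomograms; one failure does not abort.

    Returns one summary row per tomogram (name, per-stage counts, accepted
    count or error) and writes ``summary.tsv`` plus per-tomogram coordinate
    files into ``out_dir``.
    """
    if not paths:
        raise ValueError("empty tomogram list")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows: list[dict[str, Any]] = []
    for p in paths:
        p = Path(p)
        row: dict[str, Any] = {"tomogram": p.name}
        try:
            res = run_picking(
                p, config,
                out_coords=out_dir / f"{p.stem}_coords.{config.coordinate_format}",
            )
            row.update(res.stage_counts)
            row["error"] = ""
        except Exception as exc:  # noqa: BLE001 - batch must survive bad inputs
            logger.error("batch: %s failed: %s", p, exc)
            row["error"] = str(exc)
        rows.append(row)
    cols = ["tomogram", "mask_voxels", "minima", "after_mask_slab", "accepted", "error"]
    with open(out_dir / "summary.tsv", "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in rows:
            fh.write("\t".join(str(row.get(c, "")) for c in cols) + "\n")
    return rows
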