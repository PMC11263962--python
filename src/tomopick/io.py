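"""Tomogram, mask and coordinate I/O.

Volumes are MRC2014: float32 (mode 2) for tomograms, int8 (mode 0) for binary
masks, written in the standard layout (x fastest, z sections, MAPC/MAPR/MAPS =
1/2/3). In memory a volume is a ``(nz, ny, nx)`` numpy array; user-facing
coordinates are always ``(x, y, z)``, 0-based voxel centers.

Coordinates round-trip through two text dialects:

* ``tsv`` — one particle per line, ``x<TAB>y<TAB>z``, no header;
* ``star`` — a single ``data_``/``loop_`` block with the conventional
  ``_rlnCoordinateX/Y/Z`` columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

from .particles import Candidate, ParticleSet  # noqa: F401  (re-export)

__all__ = [
    "Tomogram",
    "MrcFormatError",
    "read_tomogram",
    "write_tomogram",
    "read_mask",
    "write_mask",
    "read_coordinates",
    "write_coordinates",
]

logger = logging.getLogger(__name__)


class MrcFormatError(ValueError):
    """Raised when an MRC file cannot be interpreted."""


@dataclass
class Tomogram:
    """A 3D scalar volume with its voxel spacing.

    ``voxels`` is indexed ``(z, y, x)``; ``pixel_size`` is Å per voxel and is
    assumed isotropic.
    """

    voxels: np.ndarray
    pixel_size: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3D volume, got ndim={self.voxels.ndim}")
        if any(n < 1 for n in self.voxels.shape):
            raise ValueError(f"degenerate volume shape {self.voxels.shape}")
        if not self.pixel_size > 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")
        self.origin = np.asarray(self.origin, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        """Volume shape as ``(nx, ny, nz)``."""
        nz, ny, nx = self.voxels.shape
        return (nx, ny, nz)

    def radius_voxels(self, radius_angstrom: float) -> int:
        """Convert a radius in Å to voxels (rounded, at least 1)."""
        return max(1, int(round(radius_angstrom / self.pixel_size)))


def _grid_to_zyx(grid) -> np.ndarray:
    # gemmi grids are (X, Y, Z) in memory; transpose to our (z, y, x)
    return np.array(grid, copy=True).transpose(2, 1, 0)


def _zyx_to_grid_array(vol: np.ndarray) -> np.ndarray:
    return np.ascontiguousarray(vol.transpose(2, 1, 0))


def _check_spacing(grid, path: Path, pixel_size: float | None) -> float:
    spacing = grid.spacing
    if not all(np.isfinite(s) and s > 0 for s in spacing):
        if pixel_size is None:
            raise MrcFormatError(
                f"{path}: header voxel size is {spacing}; pass pixel_size= to override"
            )
        logger.warning("%s: invalid header voxel size %s, using %.4g Å", path, spacing, pixel_size)
        return float(pixel_size)
    if max(spacing) - min(spacing) > 1e-3 * max(spacing):
        logger.warning("%s: anisotropic voxel size %s, using mean", path, spacing)
    header = float(np.mean(spacing))
    if pixel_size is not None and abs(header - pixel_size) > 1e-3 * header:
        logger.warning(
            "%s: overriding header voxel size %.4g Å with %.4g Å", path, header, pixel_size
        )
        return float(pixel_size)
    return header


def read_tomogram(path: str | Path, pixel_size: float | None = None) -> Tomogram:
    """Read an MRC2014 volume.

    Parameters
    ----------
    path
        MRC file.
    pixel_size
        Optional override in Å; required if the header voxel size is 0.

    NaN/Inf voxels are replaced by the finite-voxel mean (count logged) rather
    than rejected — reconstruction edge artifacts are common.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"tomogram not found: {path}")
    try:
        ccp4 = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError) as exc:
        raise MrcFormatError(f"{path}: not a readable MRC/CCP4 map ({exc})") from exc
    spacing = _check_spacing(ccp4.grid, path, pixel_size)
    vol = _grid_to_zyx(ccp4.grid).astype(np.float32)
    bad = ~np.isfinite(vol)
    if bad.any():
        finite_mean = float(vol[~bad].mean()) if (~bad).any() else 0.0
        vol[bad] = finite_mean
        logger.warning("%s: sanitized %d non-finite voxels", path, int(bad.sum()))
    return Tomogram(vol, spacing)


def write_tomogram(tomo: Tomogram, path: str | Path) -> None:
    """Write a Tomogram as a float32 (mode 2) MRC2014 file."""
    path = Path(path)
    grid = gemmi.FloatGrid(_zyx_to_grid_array(tomo.voxels.astype(np.float32)))
    nz, ny, nx = tomo.voxels.shape
    ps = tomo.pixel_size
    grid.unit_cell = gemmi.UnitCell(nx * ps, ny * ps, nz * ps, 90.0, 90.0, 90.0)
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = grid
    ccp4.update_ccp4_header(2, True)
    ccp4.write_ccp4_map(str(path))


def write_mask(mask: np.ndarray, pixel_size: float, path: str | Path) -> None:
    """Write a binary mask as an int8 (mode 0) MRC2014 file with values {0,1}."""
    mask = np.asarray(mask)
    if mask.dtype != bool:
        vals = np.unique(mask)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"mask is not binary: values {vals[:10]}")
        mask = mask.astype(bool)
    grid = gemmi.Int8Grid(_zyx_to_grid_array(mask.astype(np.int8)))
    nz, ny, nx = mask.shape
    grid.unit_cell = gemmi.UnitCell(nx * pixel_size, ny * pixel_size, nz * pixel_size,
                                    90.0, 90.0, 90.0)
    ccp4 = gemmi.Ccp4Mask()
    ccp4.grid = grid
    ccp4.update_ccp4_header(0, True)
    ccp4.write_ccp4_map(str(path))


def read_mask(path: str | Path) -> np.ndarray:
    """Read a binary mask written by :func:`write_mask` as a boolean array."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"mask not found: {path}")
    ccp4 = gemmi.read_ccp4_mask(str(path))
    return _grid_to_zyx(ccp4.grid).astype(bool)


_STAR_HEADER = (
    "\ndata_particles\n\nloop_\n"
    "_rlnCoordinateX #1\n_rlnCoordinateY #2\n_rlnCoordinateZ #3\n"
)


def write_coordinates(
    particles: ParticleSet | Sequence[tuple[int, int, int]],
    path: str | Path,
    format: str = "tsv",
    scale: float = 1.0,
) -> None:
    """Write accepted particle coordinates.

    ``scale`` maps voxel coordinates to a target binning (output = voxel × scale).
    A ParticleSet contributes only its accepted candidates; a plain sequence of
    ``(x, y, z)`` positions is written as-is.
    """
    if scale <= 0:
        raise ValueError(f"scale must be > 0, got {scale}")
    if format not in ("tsv", "star"):
        raise ValueError(f"unknown coordinate format {format!r}")
    if isinstance(particles, ParticleSet):
        positions: Iterable[tuple[int, int, int]] = particles.accepted_positions
    else:
        positions = particles
    positions = list(positions)
    if not positions:
        logger.warning("%s: writing empty coordinate file", path)

    def fmt(v: float) -> str:
        s = v * scale
        return str(int(s)) if float(s).is_integer() else repr(float(s))

    lines = [f"{fmt(x)}\t{fmt(y)}\t{fmt(z)}" for x, y, z in positions]
    with open(path, "w") as fh:
        if format == "star":
            fh.write(_STAR_HEADER)
        fh.write("\n".join(lines))
        if lines:
            fh.write("\n")


def read_coordinates(path: str | Path, format: str = "tsv") -> list[tuple[float, float, float]]:
    """Read coordinates written by :func:`write_coordinates` (inverse at scale 1)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"coordinate file not found: {path}")
    if format not in ("tsv", "star"):
        raise ValueError(f"unknown coordinate format {format!r}")
    positions: list[tuple[float, float, float]] = []
    in_loop = format == "tsv"
    n_cols = 0
    for lineno, raw in enumerate(open(path), start=1):
        line = raw.strip()
        if format == "star":
            if not in_loop:
                if line == "loop_":
                    in_loop = True
                continue
            if line.startswith("_"):
                n_cols += 1
                continue
            if not line or line.startswith("data_"):
                continue
        elif not line:
            continue
        tokens = line.split()
        if len(tokens) < 3:
            raise ValueError(f"{path}:{lineno}: expected 3 columns, got {len(tokens)}")
        try:
            x, y, z = (float(t) for t in tokens[:3])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-numeric coordinate ({exc})") from exc
        positions.append((x, y, z))
    return positions
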