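"""Ground-truthed phantom tomograms.

The generator emulates the inputs the picker assumes: dark, roughly spherical
particles of known radius on a noisy background, very dark high-contrast
blobs standing in for gold fiducials / ice contamination, an optional dark
membrane-like sheet, and a finite-thickness sample slab. Everything is a pure
function of the :class:`PhantomSpec` (including its seed).

Particles use a cosine-tapered radial profile (``depth * 0.5*(1+cos(pi d/r))``
for ``d <= r``) rather than a hard binary sphere, so low-passed minima are
well defined. The membrane is a dark sheet with normal along y, optional
sinusoidal corrugation, and a cosine-tapered cross-section — electron-dense
structures are dark under the same contrast convention that makes particles
dark, and a dark sheet is exactly what produces the false-positive minima the
background criterion exists to remove. The missing wedge is not modeled; an
optional anisotropic z-smear (``z_smear_sigma``) probes robustness to
z-elongation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import ndimage

from .io import Tomogram

__all__ = [
    "MembraneSpec",
    "PhantomSpec",
    "GroundTruth",
    "SnrReport",
    "generate_phantom",
    "snr_report",
    "EASY_INVITRO",
    "INSITU_LIKE",
]

logger = logging.getLogger(__name__)

_MAX_TRIES = 20000


@dataclass
class MembraneSpec:
    """A membrane-like sheet: plane y = y0 + amp*sin(2*pi*x/period), tapered."""

    amplitude: float = -1.5
    thickness_voxels: float = 10.0
    y_fraction: float = 0.5
    curvature_amplitude_voxels: float = 0.0
    curvature_period_voxels: float = 64.0


@dataclass
class PhantomSpec:
    """Full description of a phantom; the output is a pure function of it."""

    shape: tuple[int, int, int] = (96, 96, 96)  # (nx, ny, nz)
    pixel_size: float = 10.0
    n_particles: int = 20
    particle_radius_angstrom: float = 60.0
    particle_depth: float = -1.0
    min_separation_factor: float = 2.5
    slab_fraction: float = 1.0
    noise_sigma: float = 0.3
    n_fiducials: int = 2
    fiducial_radius_angstrom: float = 30.0
    fiducial_depth: float = -12.0
    membrane: MembraneSpec | None = None
    z_smear_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_particles < 0 or self.n_fiducials < 0:
            raise ValueError("counts must be >= 0")
        if not (0 < self.slab_fraction <= 1):
            raise ValueError("slab_fraction must be in (0, 1]")
        if self.particle_radius_angstrom <= 0 or self.pixel_size <= 0:
            raise ValueError("radius and pixel size must be > 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    @property
    def radius_voxels(self) -> int:
        return max(1, int(round(self.particle_radius_angstrom / self.pixel_size)))

    @property
    def fiducial_radius_voxels(self) -> int:
        return max(1, int(round(self.fiducial_radius_angstrom / self.pixel_size)))


@dataclass
class GroundTruth:
    """True particle centers plus feature geometry for evaluation."""

    particle_positions: list[tuple[int, int, int]]  # (x, y, z)
    fiducial_positions: list[tuple[int, int, int]]
    feature_mask: np.ndarray  # True where any synthetic structure was painted
    spec: PhantomSpec


@dataclass
class SnrReport:
    nominal_snr: float
    center_contrast: float  # mean (filtered bg mean - filtered value at center)
    background_std: float  # std of the filtered volume outside features
    empirical_snr: float


def _paint_sphere(vol: np.ndarray, center_zyx: tuple[int, int, int], radius: float,
                  depth: float) -> None:
    """Add a cosine-tapered sphere in place."""
    cz, cy, cx = center_zyx
    r_int = int(np.ceil(radius))
    nz, ny, nx = vol.shape
    z0, z1 = max(0, cz - r_int), min(nz, cz + r_int + 1)
    y0, y1 = max(0, cy - r_int), min(ny, cy + r_int + 1)
    x0, x1 = max(0, cx - r_int), min(nx, cx + r_int + 1)
    zz, yy, xx = np.mgrid[z0:z1, y0:y1, x0:x1]
    d = np.sqrt((zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2)
    inside = d <= radius
    profile = np.where(inside, 0.5 * (1.0 + np.cos(np.pi * np.minimum(d / radius, 1.0))), 0.0)
    vol[z0:z1, y0:y1, x0:x1] += depth * profile


def _membrane_field(shape_zyx: tuple[int, int, int], mem: MembraneSpec) -> np.ndarray:
    nz, ny, nx = shape_zyx
    y0 = mem.y_fraction * (ny - 1)
    xs = np.arange(nx, dtype=float)
    if mem.curvature_amplitude_voxels:
        y_sheet = y0 + mem.curvature_amplitude_voxels * np.sin(
            2.0 * np.pi * xs / mem.curvature_period_voxels
        )
    else:
        y_sheet = np.full(nx, y0)
    ys = np.arange(ny, dtype=float)
    dy = np.abs(ys[:, None] - y_sheet[None, :])  # (ny, nx)
    half = mem.thickness_voxels / 2.0
    taper = 2.0  # voxels of soft edge beyond the half-thickness
    prof = np.clip((half + taper - dy) / taper, 0.0, 1.0)
    prof = np.where(dy <= half, 1.0, prof * (dy <= half + taper))
    field = mem.amplitude * prof  # (ny, nx)
    return np.broadcast_to(field, (nz, ny, nx)).copy()


def _membrane_distance(pos_zyx: tuple[int, int, int], shape_zyx: tuple[int, int, int],
                       mem: MembraneSpec) -> float:
    _, ny, nx = shape_zyx
    z, y, x = pos_zyx
    y0 = mem.y_fraction * (ny - 1)
    if mem.curvature_amplitude_voxels:
        y0 = y0 + mem.curvature_amplitude_voxels * np.sin(
            2.0 * np.pi * x / mem.curvature_period_voxels
        )
    return abs(y - y0)


def generate_phantom(spec: PhantomSpec) -> tuple[Tomogram, GroundTruth]:
    """Build the phantom volume and its ground truth.

    Particle centers are rejection-sampled: inside the slab, away from volume
    faces by the filtering-subvolume half-width, pairwise separation
    >= ``min_separation_factor * r``, clear of fiducial surfaces by ``r`` and
    of the membrane sheet by ``r + thickness/2``. Raises if the constraint
    cannot be met within the retry budget.
    """
    rng = np.random.default_rng(spec.seed)
    nx, ny, nz = spec.shape
    shape_zyx = (nz, ny, nx)
    vol = np.zeros(shape_zyx, dtype=np.float64)
    r = spec.radius_voxels
    fid_r = spec.fiducial_radius_voxels

    # margin so the (3r)^3 filtering subvolume fits around every true center
    side = 3 * r + (0 if (3 * r) % 2 else 1)
    margin = side // 2 + 1

    # fiducials first: anywhere with a small margin, mutually separated
    fiducials: list[tuple[int, int, int]] = []
    for _ in range(_MAX_TRIES):
        if len(fiducials) == spec.n_fiducials:
            break
        p = tuple(int(rng.integers(fid_r + 1, n - fid_r - 1)) for n in (nz, ny, nx))
        if all(np.linalg.norm(np.subtract(p, q)) >= 2.5 * fid_r for q in fiducials):
            fiducials.append(p)  # (z, y, x)
    if len(fiducials) < spec.n_fiducials:
        raise RuntimeError("could not place fiducials; reduce n_fiducials")

    slab_half = spec.slab_fraction * nz / 2.0
    z_lo = max(margin, int(np.ceil(nz / 2.0 - slab_half)))
    z_hi = min(nz - margin, int(np.floor(nz / 2.0 + slab_half)) + 1)
    if z_hi <= z_lo:
        raise ValueError("slab too thin for the volume margins")

    min_sep = spec.min_separation_factor * r
    particles: list[tuple[int, int, int]] = []  # (z, y, x)
    tries = 0
    while len(particles) < spec.n_particles:
        tries += 1
        if tries > _MAX_TRIES:
            raise RuntimeError(
                f"placed only {len(particles)}/{spec.n_particles} particles under the "
                "separation constraint; reduce n_particles or the separation factor"
            )
        p = (
            int(rng.integers(z_lo, z_hi)),
            int(rng.integers(margin, ny - margin)),
            int(rng.integers(margin, nx - margin)),
        )
        if any(np.linalg.norm(np.subtract(p, q)) < min_sep for q in particles):
            continue
        # clearance: a particle whose blurred support overlaps another dark
        # feature's skirt has no size-scale minimum of its own (the minimum
        # slides into the deeper valley), so such placements are unresolvable
        # by construction. Reach of a feature after the detection low-pass
        # (sigma = r/2) is ~ its support + r, hence the 2r terms.
        if any(np.linalg.norm(np.subtract(p, q)) < fid_r + 2 * r + 2 for q in fiducials):
            continue
        if spec.membrane is not None:
            if _membrane_distance(p, shape_zyx, spec.membrane) < (
                2 * r + spec.membrane.thickness_voxels / 2.0 + 4.0
            ):
                continue
        particles.append(p)

    for p in particles:
        _paint_sphere(vol, p, float(r), spec.particle_depth)
    for p in fiducials:
        _paint_sphere(vol, p, float(fid_r), spec.fiducial_depth)
    if spec.membrane is not None:
        vol += _membrane_field(shape_zyx, spec.membrane)

    feature_mask = vol != 0.0
    if spec.z_smear_sigma > 0:
        vol = ndimage.gaussian_filter1d(vol, spec.z_smear_sigma, axis=0, mode="nearest")
    if spec.noise_sigma > 0:
        vol = vol + rng.normal(0.0, spec.noise_sigma, size=shape_zyx)

    truth = GroundTruth(
        particle_positions=[(x, y, z) for z, y, x in particles],
        fiducial_positions=[(x, y, z) for z, y, x in fiducials],
        feature_mask=feature_mask,
        spec=spec,
    )
    return Tomogram(vol.astype(np.float32), spec.pixel_size), truth


def snr_report(tomo: Tomogram, truth: GroundTruth,
               sigma_factor: float = 0.5) -> SnrReport:
    """Nominal and empirical contrast of the phantom's particles.

    Nominal SNR is ``|particle_depth| / noise_sigma`` (inf when noiseless).
    Empirical contrast is measured on the detection-low-passed volume: mean
    over true centers of (background mean - center value), with the background
    taken outside all painted features; empirical SNR divides by the filtered
    background std.
    """
    spec = truth.spec
    nominal = (
        float("inf") if spec.noise_sigma == 0 else abs(spec.particle_depth) / spec.noise_sigma
    )
    from .preprocess import lowpass_for_detection

    filt = lowpass_for_detection(tomo, spec.radius_voxels, sigma_factor).voxels
    bg = filt[~truth.feature_mask]
    bg_mean = float(bg.mean())
    bg_std = float(bg.std())
    center_vals = [filt[z, y, x] for x, y, z in truth.particle_positions]
    contrast = float(bg_mean - np.mean(center_vals)) if center_vals else 0.0
    empirical = contrast / bg_std if bg_std > 0 else float("inf")
    return SnrReport(nominal, contrast, bg_std, empirical)


# Shipped phantom specs. easy_invitro emulates a clean in-vitro field of
# high-contrast particles with a couple of fiducials; insitu_like adds a dark
# membrane-like sheet through a crowded field.
EASY_INVITRO = PhantomSpec(
    shape=(96, 96, 96),
    pixel_size=10.0,
    n_particles=20,
    particle_radius_angstrom=60.0,
    particle_depth=-1.0,
    min_separation_factor=2.5,
    noise_sigma=0.3,
    n_fiducials=2,
    fiducial_radius_angstrom=30.0,
    fiducial_depth=-12.0,
    seed=11,
)

INSITU_LIKE = PhantomSpec(
    shape=(112, 112, 96),
    pixel_size=10.0,
    n_particles=30,
    particle_radius_angstrom=60.0,
    particle_depth=-1.0,
    min_separation_factor=2.5,
    noise_sigma=0.35,
    n_fiducials=2,
    fiducial_radius_angstrom=30.0,
    fiducial_depth=-12.0,
    membrane=MembraneSpec(
        amplitude=-1.3,
        thickness_voxels=12.0,
        y_fraction=0.3,
        curvature_amplitude_voxels=4.0,
        curvature_period_voxels=80.0,
    ),
    seed=23,
)

SHIPPED_SPECS: dict[str, PhantomSpec] = {
    "easy_invitro": EASY_INVITRO,
    "insitu_like": INSITU_LIKE,
}
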