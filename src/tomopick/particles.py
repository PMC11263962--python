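"""Particle candidates and picked-particle sets.

Coordinates are 0-based voxel centers reported as ``(x, y, z)``; volumes are
indexed internally as ``(z, y, x)`` with x the fastest axis (the MRC layout).
A :class:`Candidate` moves through exactly one status transition,
``candidate -> accepted`` or ``candidate -> rejected_*``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any, Iterable, Iterator

__all__ = [
    "Candidate",
    "ParticleSet",
    "STATUS_CANDIDATE",
    "STATUS_ACCEPTED",
    "STATUS_REJECTED_MASK",
    "STATUS_REJECTED_STAT",
    "STATUS_REJECTED_SLAB",
    "STATUS_REJECTED_BOUNDARY",
    "ALL_STATUSES",
]

STATUS_CANDIDATE = "candidate"
STATUS_ACCEPTED = "accepted"
STATUS_REJECTED_MASK = "rejected_mask"
STATUS_REJECTED_STAT = "rejected_stat"
STATUS_REJECTED_SLAB = "rejected_slab"
STATUS_REJECTED_BOUNDARY = "rejected_boundary"

ALL_STATUSES = frozenset(
    {
        STATUS_CANDIDATE,
        STATUS_ACCEPTED,
        STATUS_REJECTED_MASK,
        STATUS_REJECTED_STAT,
        STATUS_REJECTED_SLAB,
        STATUS_REJECTED_BOUNDARY,
    }
)


@dataclass
class Candidate:
    """One candidate particle position.

    Parameters
    ----------
    position
        ``(x, y, z)`` integer voxel coordinates, 0-based.
    density
        Gray value of the detection volume at ``position``.
    fg_std, bg_std
        Foreground/background standard deviations of the local Z-projection,
        filled by the filtering stage (``None`` until then).
    status
        One of the ``STATUS_*`` constants.
    reason
        Free-text sub-reason for a rejection (e.g. ``"threshold"`` or
        ``"background"`` for ``rejected_stat``).
    """

    position: tuple[int, int, int]
    density: float
    fg_std: float | None = None
    bg_std: float | None = None
    status: str = STATUS_CANDIDATE
    reason: str = ""

    def __post_init__(self) -> None:
        self.position = tuple(int(c) for c in self.position)  # type: ignore[assignment]
        if self.status not in ALL_STATUSES:
            raise ValueError(f"unknown candidate status {self.status!r}")

    @property
    def zyx(self) -> tuple[int, int, int]:
        """Position in array index order."""
        x, y, z = self.position
        return (z, y, x)

    def with_status(self, status: str, reason: str = "") -> "Candidate":
        if self.status != STATUS_CANDIDATE and status != self.status:
            raise ValueError(
                f"illegal status transition {self.status!r} -> {status!r}"
            )
        return replace(self, status=status, reason=reason)


@dataclass
class ParticleSet:
    """An ordered collection of candidates plus the radius they were picked at."""

    candidates: list[Candidate] = field(default_factory=list)
    radius_voxels: int = 1
    radius_angstrom: float = 1.0
    provenance: dict[str, Any] = field(default_factory=dict)

    def __iter__(self) -> Iterator[Candidate]:
        return iter(self.candidates)

    def __len__(self) -> int:
        return len(self.candidates)

    @property
    def accepted(self) -> list[Candidate]:
        return [c for c in self.candidates if c.status == STATUS_ACCEPTED]

    @property
    def accepted_positions(self) -> list[tuple[int, int, int]]:
        return [c.position for c in self.accepted]

    def count_by_status(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for c in self.candidates:
            counts[c.status] = counts.get(c.status, 0) + 1
        return counts


def positions_xyz(candidates: Iterable[Candidate]) -> list[tuple[int, int, int]]:
    return [c.position for c in candidates]
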