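"""Independent brute-force oracles used to cross-check the implementation.

Deliberately written with different algorithms/code paths than the package:
explicit window scans, BFS flood fill, dense-kernel convolution, selection-
based suppression, and optimal assignment.
"""

from __future__ import annotations

from collections import deque

import numpy as np
from scipy.optimize import linear_sum_assignment


def strict_minima_oracle(vol: np.ndarray, h: int) -> set[tuple[int, int, int]]:
    """Every voxel strictly smaller than all others in its clipped window.

    Returns positions as (x, y, z). Exhaustive per-voxel window scan.
    """
    side = 2 * (h // 2) + 1
    half = side // 2
    nz, ny, nx = vol.shape
    out: set[tuple[int, int, int]] = set()
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                v = vol[z, y, x]
                win = vol[
                    max(0, z - half) : z + half + 1,
                    max(0, y - half) : y + half + 1,
                    max(0, x - half) : x + half + 1,
                ]
                if (win < v).sum() == 0 and (win == v).sum() == 1:
                    out.add((x, y, z))
    return out


def suppression_oracle(
    positions: list[tuple[int, int, int]], densities: list[float], min_dist: float
) -> list[tuple[int, int, int]]:
    """Selection-based darkest-first suppression (O(n^2)).

    Repeatedly takes the globally darkest remaining point (ties by position)
    and removes every remaining point strictly closer than ``min_dist``.
    """
    remaining = sorted(zip(densities, positions))
    kept: list[tuple[int, int, int]] = []
    while remaining:
        _, best = remaining.pop(0)
        kept.append(best)
        remaining = [
            (d, p)
            for d, p in remaining
            if sum((a - b) ** 2 for a, b in zip(p, best)) >= min_dist**2
        ]
    return kept


def flood_fill_components(mask: np.ndarray) -> list[set[tuple[int, int, int]]]:
    """26-connected components by BFS; returns a list of voxel sets."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    comps: list[set[tuple[int, int, int]]] = []
    offsets = [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ]
    nz, ny, nx = mask.shape
    for start in zip(*np.nonzero(mask & ~seen)):
        if seen[start]:
            continue
        comp: set[tuple[int, int, int]] = set()
        queue = deque([start])
        seen[start] = True
        while queue:
            z, y, x = queue.popleft()
            comp.add((z, y, x))
            for dz, dy, dx in offsets:
                p = (z + dz, y + dy, x + dx)
                if 0 <= p[0] < nz and 0 <= p[1] < ny and 0 <= p[2] < nx:
                    if mask[p] and not seen[p]:
                        seen[p] = True
                        queue.append(p)
        comps.append(comp)
    return comps


def gaussian_kernel_1d(sigma: float, truncate: float = 4.0) -> np.ndarray:
    """The discrete Gaussian kernel scipy.ndimage uses (normalized, radius
    int(truncate*sigma + 0.5))."""
    radius = int(truncate * sigma + 0.5)
    x = np.arange(-radius, radius + 1)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def dense_gaussian_convolve(vol: np.ndarray, sigma: float) -> np.ndarray:
    """Direct spatial convolution with the full 3D kernel, edge replication."""
    k1 = gaussian_kernel_1d(sigma)
    kernel = k1[:, None, None] * k1[None, :, None] * k1[None, None, :]
    r = len(k1) // 2
    padded = np.pad(vol.astype(np.float64), r, mode="edge")
    win = np.lib.stride_tricks.sliding_window_view(padded, kernel.shape)
    return np.einsum("zyxijk,ijk->zyx", win, kernel)


def projection_oracle(vol: np.ndarray, center_xyz, half: int) -> np.ndarray:
    """Slice-by-slice accumulation of the z-mean projection."""
    x, y, z = center_xyz
    acc = np.zeros((2 * half + 1, 2 * half + 1), dtype=np.float64)
    n = 0
    for zz in range(z - half, z + half + 1):
        acc += vol[zz, y - half : y + half + 1, x - half : x + half + 1]
        n += 1
    return acc / n


def two_pass_std(values) -> float:
    """Two-pass population standard deviation."""
    vals = list(float(v) for v in values)
    n = len(vals)
    mean = sum(vals) / n
    return (sum((v - mean) ** 2 for v in vals) / n) ** 0.5


def max_matching_size(pred, truth, threshold: float) -> int:
    """Maximum-cardinality one-to-one matching within distance threshold.

    Optimal assignment on a 0/1 cost matrix (0 = pair within threshold),
    padded to square so unmatchable points absorb the invalid cost.
    """
    p = np.asarray(pred, float)
    t = np.asarray(truth, float)
    if len(p) == 0 or len(t) == 0:
        return 0
    d = np.linalg.norm(p[:, None, :] - t[None, :, :], axis=2)
    n = max(len(p), len(t))
    cost = np.ones((n, n))
    cost[: len(p), : len(t)] = (d > threshold).astype(float)
    rows, cols = linear_sum_assignment(cost)
    return int(sum(cost[r, c] == 0 for r, c in zip(rows, cols)))
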