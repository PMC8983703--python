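"""Independent reference implementations used only as test oracles.

Each function here recomputes a quantity through a different route than
the library (explicit coefficient sums instead of recurrences, string
scanning instead of array logic, exhaustive enumeration instead of spatial
pruning), so agreement is evidence of correctness rather than repetition.
"""

from __future__ import annotations

import re

import numpy as np
from scipy.special import binom, factorial, lpmv


def radial_reference(n: int, l: int, r: np.ndarray) -> np.ndarray:
    """Canterakis radial polynomial via the explicit coefficient sum."""
    k = (n - l) // 2
    r = np.asarray(r, dtype=float)
    out = np.zeros_like(r)
    for nu in range(k + 1):
        q = (
            ((-1) ** (k + nu) / 4.0**k)
            * np.sqrt(2 * l + 4 * k + 3)
            * binom(2 * k, k)
            * binom(k, nu)
            * binom(2 * (k + l + nu) + 1, 2 * k)
            / binom(k + l + nu, k)
        )
        out = out + q * r ** (2 * nu + l)
    return out


def ylm_reference(l: int, m: int, theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Orthonormal spherical harmonic from associated Legendre + factorials."""
    am = abs(m)
    norm = np.sqrt((2 * l + 1) / (4 * np.pi) * factorial(l - am) / factorial(l + am))
    base = norm * lpmv(am, l, np.cos(theta)) * np.exp(1j * am * phi)
    return base if m >= 0 else (-1) ** am * np.conj(base)


def moments_reference(points: np.ndarray, weights: np.ndarray, order: int) -> dict:
    """Direct evaluation of the moment projection, point by point."""
    points = np.asarray(points, dtype=float)
    weights = np.broadcast_to(np.asarray(weights, dtype=float), (len(points),))
    r = np.linalg.norm(points, axis=1)
    theta = np.arccos(np.divide(points[:, 2], r, out=np.zeros(len(r)), where=r > 0))
    phi = np.arctan2(points[:, 1], points[:, 0])
    out = {}
    pref = 3.0 / (4.0 * np.pi)
    for n in range(order + 1):
        for l in range(n % 2, n + 1, 2):
            for m in range(-l, l + 1):
                z = radial_reference(n, l, r) * ylm_reference(l, m, theta, phi)
                out[(n, l, m)] = pref * np.sum(weights * np.conj(z))
    return out


def confident_regions_reference(
    values: np.ndarray, plddt_min: float = 70.0, min_run: int = 50, merge_gap: int = 5
) -> list[tuple[int, int]]:
    """Domain extraction by regex scanning of the confidence bitstring."""
    bits = "".join("1" if v > plddt_min else "0" for v in values)
    runs = [
        (m.start(), m.end())
        for m in re.finditer(r"1+", bits)
        if m.end() - m.start() > min_run
    ]
    merged: list[list[int]] = []
    for a, b in runs:
        if merged and a - merged[-1][1] <= merge_gap:
            merged[-1][1] = b
        else:
            merged.append([a, b])
    return [(a + 1, b) for a, b in merged]


def voxel_occupancy_reference(
    triangles: np.ndarray, origin: np.ndarray, spacing: float, N: int, cutoff: float
) -> np.ndarray:
    """Exhaustive voxelization: every center against every triangle."""
    from zernsurf.surface import point_triangle_distance

    grid = np.zeros((N, N, N), dtype=np.uint8)
    idx = np.stack(np.meshgrid(*[np.arange(N)] * 3, indexing="ij"), axis=-1).reshape(-1, 3)
    centers = origin + idx * spacing
    best = np.full(len(centers), np.inf)
    for tri in triangles:
        best = np.minimum(best, point_triangle_distance(centers, tri))
    occ = best < cutoff * spacing
    grid[idx[:, 0], idx[:, 1], idx[:, 2]] = occ
    return grid
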