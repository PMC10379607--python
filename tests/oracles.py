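"""Independent brute-force oracles the implementation is checked against.

These deliberately avoid the library's own code paths: the RMSD oracle
scans a dense rotation grid, the contact oracle enumerates all pairs with
plain loops, and the k-means oracle enumerates every partition.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.spatial.transform import Rotation


def grid_rmsd(x: np.ndarray, y: np.ndarray, step_deg: float = 2.0) -> float:
    """Minimum RMSD over a dense Euler-angle grid of rotations (after centering).

    Upper-bounds the true minimum by at most ~r_max * step (radians); the
    Kabsch value must lie at or below this within that slack.
    """
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    a = np.deg2rad(np.arange(0.0, 360.0, step_deg))
    b = np.deg2rad(np.arange(0.0, 180.0, step_deg))
    angles = np.array(list(itertools.product(a, b, a)))
    mats = Rotation.from_euler("zyz", angles).as_matrix()
    rotated = np.einsum("rij,nj->rni", mats, xc)
    d2 = np.mean(np.sum((rotated - yc) ** 2, axis=2), axis=1)
    return float(np.sqrt(d2.min()))


def brute_contacts(coords: np.ndarray, cutoff: float, min_sep: int) -> set[tuple[int, int]]:
    """All contact pairs by an explicit O(n²) double loop."""
    n = len(coords)
    sep = max(1, min_sep)
    out = set()
    for i in range(n):
        for j in range(i + 1, n):
            if j - i >= sep and math.dist(coords[i], coords[j]) <= cutoff:
                out.add((i, j))
    return out


def brute_fnc(coords: np.ndarray, pairs, cutoff: float) -> float:
    """Recount surviving contacts pair by pair."""
    alive = sum(1 for i, j in pairs if math.dist(coords[i], coords[j]) <= cutoff)
    return alive / len(pairs)


def brute_kmeans_inertia(points: np.ndarray, weights: np.ndarray, k: int) -> float:
    """Exact optimal weighted inertia by enumerating all label assignments."""
    n = len(points)
    best = np.inf
    for labels in itertools.product(range(k), repeat=n):
        labels = np.asarray(labels)
        total = 0.0
        for c in range(k):
            m = labels == c
            if not m.any():
                continue
            w = weights[m]
            center = np.average(points[m], axis=0, weights=w)
            total += float(np.sum(w * np.sum((points[m] - center) ** 2, axis=1)))
        best = min(best, total)
    return best


def brute_tuple_table(frame_coords, fnc_values, rep_of):
    """All unordered frame-pair tuples by explicit loops (all_cross pairing).

    ``frame_coords`` are already in canonical order; RMSD is computed with
    an independent quaternion-free direct SVD on the pair.
    """
    from scipy.spatial.transform import Rotation

    rows = []
    n = len(frame_coords)
    for i in range(n):
        for j in range(i + 1, n):
            p = frame_coords[i] - frame_coords[i].mean(axis=0)
            q = frame_coords[j] - frame_coords[j].mean(axis=0)
            rot, rssd = Rotation.align_vectors(q, p)
            rows.append(
                (rssd / np.sqrt(len(p)), fnc_values[i], fnc_values[j], rep_of[i], rep_of[j])
            )
    return rows
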