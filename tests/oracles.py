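"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths they verify: the DBSCAN oracle works
from an explicit O(n^2) neighbour matrix with breadth-first expansion, and
the MIP oracle takes an explicit slab maximum per output slice.
"""

from __future__ import annotations

import numpy as np


def dbscan_bruteforce(points: np.ndarray, eps: float, min_samples: int):
    """Classic single-pass DBSCAN from a full neighbour matrix.

    Returns an integer label per point (-1 for noise); clusters are numbered
    in discovery (input) order and border points belong to the cluster that
    reached them first.
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    if n == 0:
        return np.empty(0, dtype=int)
    diff = points[:, None, :] - points[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=-1))
    neighbours = dist <= eps
    core = neighbours.sum(axis=1) >= min_samples
    labels = np.full(n, -2, dtype=int)  # -2 unvisited, -1 noise
    cluster = 0
    for i in range(n):
        if labels[i] != -2 or not core[i]:
            continue
        labels[i] = cluster
        frontier = [i]
        while frontier:
            j = frontier.pop(0)
            for k in np.flatnonzero(neighbours[j]):
                if labels[k] in (-2, -1):
                    labels[k] = cluster
                    if core[k]:
                        frontier.append(k)
        cluster += 1
    labels[labels == -2] = -1
    return labels


def partition_of(labels) -> tuple[frozenset, set]:
    """Canonical form of a clustering: set of member-index clusters + noise."""
    labels = np.asarray(labels)
    clusters = frozenset(
        frozenset(np.flatnonzero(labels == c).tolist())
        for c in np.unique(labels) if c >= 0
    )
    noise = set(np.flatnonzero(labels == -1).tolist())
    return clusters, noise


def mip_bruteforce(voxels: np.ndarray, axis_dim: int, window_mm: float,
                   voxel_mm: float = 1.0) -> np.ndarray:
    """Per-output-slice slab maximum: for each plane k along ``axis_dim``,
    take the max over planes whose centres lie within the closed window
    ``[k*voxel - w/2, k*voxel + w/2]``, clipped at the boundary."""
    n = voxels.shape[axis_dim]
    half = int(np.floor(window_mm / (2.0 * voxel_mm) + 1e-9))
    moved = np.moveaxis(voxels, axis_dim, 0)
    out = np.empty_like(moved)
    for k in range(n):
        lo, hi = max(0, k - half), min(n, k + half + 1)
        out[k] = moved[lo:hi].max(axis=0)
    return np.moveaxis(out, 0, axis_dim)
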