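"""Spatial windowing: balanced clustering for grid placement, then kNN windows.

The tissue is partitioned into P = floor(N/S) equal-size (±1) spatial
clusters; each cluster centroid becomes a grid point, and the window at a grid
point is the Q units nearest to it.  Windows overlap: with the defaults S=5 and
Q=25 each unit is covered by Q/S = 5 windows on average, which keeps adjacent
local fits smoothly varying across the tissue.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import kmeans_plusplus

from .types import LsgiConfig, SpatialProfile

_MAX_BALANCE_ITER = 50


@dataclass
class GridScaffold:
    """P grid points with their Q-member windows.

    ``members[i]`` lists the unit indices of the window at grid point ``i``,
    ordered by ascending distance to the grid coordinate (ties by ascending
    unit index).
    """

    grid_coords: np.ndarray  # (P, 2)
    members: list[np.ndarray]
    p: int
    q: int

    def __post_init__(self) -> None:
        self.grid_coords = np.asarray(self.grid_coords, dtype=float)
        if self.grid_coords.shape != (self.p, 2):
            raise ValueError("grid_coords must be (P, 2)")
        if len(self.members) != self.p:
            raise ValueError("one member list required per grid point")

    def membership_counts(self, n_units: int) -> np.ndarray:
        """How many windows each unit belongs to."""
        counts = np.zeros(n_units, dtype=int)
        for m in self.members:
            counts[m] += 1
        return counts


def _balanced_assign(coords: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """Greedy equal-size assignment: fill clusters by globally ascending
    unit-to-centroid distance, capacity ceil(N/P) per cluster."""
    n, p = coords.shape[0], centroids.shape[0]
    cap = int(np.ceil(n / p))
    d2 = ((coords[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    order = np.argsort(d2, axis=None, kind="stable")
    assign = np.full(n, -1, dtype=int)
    remaining = np.full(p, cap, dtype=int)
    n_left = n
    for flat in order:
        unit, cluster = divmod(int(flat), p)
        if assign[unit] >= 0 or remaining[cluster] == 0:
            continue
        assign[unit] = cluster
        remaining[cluster] -= 1
        n_left -= 1
        if n_left == 0:
            break
    return assign


def balanced_centroids(coords: np.ndarray, p: int, seed: int = 0) -> np.ndarray:
    """Place ``p`` grid points as centroids of equal-size spatial clusters.

    Balanced k-means: k-means++ initialization, then alternate
    capacity-constrained assignment (capacity ceil(N/P), units claimed in
    ascending distance order) with centroid updates, to convergence or 50
    iterations.  Deterministic given ``seed``.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if p < 1:
        raise ValueError("p must be >= 1")
    if p > n:
        raise ValueError(f"cannot place {p} grid points over {n} units")
    if np.allclose(coords, coords[0]):
        warnings.warn("all units share one coordinate; grid points coincide")
        return np.tile(coords[0], (p, 1))
    if p == n:
        return coords.copy()

    rng = np.random.RandomState(seed)
    centroids, _ = kmeans_plusplus(coords, n_clusters=p, random_state=rng)
    seen: list[np.ndarray] = []
    for _ in range(_MAX_BALANCE_ITER):
        assign = _balanced_assign(coords, centroids)
        new_centroids = np.vstack(
            [coords[assign == k].mean(axis=0) for k in range(p)]
        )
        shift = np.abs(new_centroids - centroids).max()
        centroids = new_centroids
        # stop on convergence or when the assignment cycles (period ≤ 2)
        if shift < 1e-9 or any(np.array_equal(assign, a) for a in seen):
            break
        seen = [assign, *seen][:2]
    return centroids


def build_grid_scaffold(profile: SpatialProfile, config: LsgiConfig) -> GridScaffold:
    """Build the grid scaffold for a profile: P = max(1, floor(N/S)) grid
    points with the Q nearest units each (Q capped at N)."""
    n = profile.n_units
    if n < 3:
        raise ValueError("gradient windows need at least 3 units")
    p = max(1, n // config.s)
    q = config.q
    if q > n:
        warnings.warn(f"q={q} exceeds N={n}; capping window size at N")
        q = n
    centroids = balanced_centroids(profile.coords, p, seed=config.seed)
    members = _knn_members(profile.coords, centroids, q)
    return GridScaffold(grid_coords=centroids, members=members, p=p, q=q)


def _knn_members(
    coords: np.ndarray, centroids: np.ndarray, q: int
) -> list[np.ndarray]:
    """Q nearest units to each centroid, distance ties broken by ascending
    unit index.  Exact pairwise distances (chunked over centroids) so tie
    handling at the k-th neighbor boundary is fully deterministic — on
    regular lattices such ties are common."""
    members: list[np.ndarray] = []
    n = coords.shape[0]
    idx = np.arange(n)
    chunk = max(1, int(2e7) // max(n, 1))
    for start in range(0, centroids.shape[0], chunk):
        block = centroids[start : start + chunk]
        d2 = ((block[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)
        for row in d2:
            order = np.lexsort((idx, row))[:q]
            members.append(order.astype(int))
    return members
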