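"""Spatial relationships between gradients and with tumor annotation.

Two quantities summarize how gradients sit in the tissue: an asymmetric
program-to-program distance — for each grid point carrying gradient A, the
distance to the nearest grid point carrying gradient B, averaged over A's grid
points — and per-window tumor ratios that place each gradient relative to the
tumor core, the tumor–microenvironment boundary, or normal tissue.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .gradients import GradientField
from .gridding import GridScaffold
from .types import SpatialProfile, TumorLabels


@dataclass
class GradientDistanceMatrix:
    """Directed distances between retained gradients, in input units.

    ``d[i, j]`` is the mean, over grid points carrying feature i, of the
    distance to the nearest grid point carrying feature j.  Generally
    ``d[i, j] != d[j, i]``: a small patch A inside a large field B is close
    to B everywhere, while most of B is far from A.
    """

    features: list[str]
    d: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.features, columns=self.features)

    def log_transformed(self, eps: float | None = None) -> pd.DataFrame:
        """Natural log of (distance + eps) for heatmap display; eps defaults
        to half the smallest nonzero distance.  Plot-layer only — the raw
        distances are what the matrix stores."""
        nonzero = self.d[self.d > 0]
        if eps is None:
            eps = float(nonzero.min()) / 2.0 if nonzero.size else 1.0
        return pd.DataFrame(
            np.log(self.d + eps), index=self.features, columns=self.features
        )


def directed_gradient_distance(grids_a: np.ndarray, grids_b: np.ndarray) -> float:
    """Mean over A's grid points of the Euclidean distance to B's nearest
    grid point.  Asymmetric by construction."""
    grids_a = np.atleast_2d(np.asarray(grids_a, dtype=float))
    grids_b = np.atleast_2d(np.asarray(grids_b, dtype=float))
    if grids_a.size == 0:
        raise ValueError("source gradient has no grid points")
    if grids_b.size == 0:
        raise ValueError("target gradient has no grid points")
    tree = cKDTree(grids_b)
    nearest, _ = tree.query(grids_a, k=1)
    return float(np.mean(nearest))


def gradient_distance_matrix(field: GradientField) -> GradientDistanceMatrix:
    """Pairwise directed distances between all retained features."""
    feats = list(field.retained_features)
    if not feats:
        raise ValueError("no retained features; nothing to relate")
    coords = {f: field.retained_grid_coords(f) for f in feats}
    n = len(feats)
    d = np.zeros((n, n))
    for i, fa in enumerate(feats):
        for j, fb in enumerate(feats):
            if i != j:
                d[i, j] = directed_gradient_distance(coords[fa], coords[fb])
    return GradientDistanceMatrix(features=feats, d=d)


def grid_tumor_ratio(scaffold: GridScaffold, labels: TumorLabels,
                     profile: SpatialProfile) -> np.ndarray:
    """Per grid point, the fraction of window members labeled tumor."""
    mask = labels.aligned_to(profile)
    return np.array([mask[m].mean() for m in scaffold.members])


def program_mean_tumor_ratio(
    field: GradientField, grid_ratio: np.ndarray
) -> dict[str, float]:
    """Unweighted mean of the grid tumor ratio over each retained feature's
    gradient-bearing grid points."""
    grid_ratio = np.asarray(grid_ratio, dtype=float)
    if grid_ratio.shape[0] != field.scaffold.p:
        raise ValueError("grid_ratio length does not match scaffold")
    out: dict[str, float] = {}
    for feat in field.retained_features:
        grids = field.retained.loc[field.retained["feature"] == feat, "grid_id"]
        if grids.empty:
            warnings.warn(f"feature {feat} has no retained grids; excluded")
            continue
        out[feat] = float(grid_ratio[grids.to_numpy()].mean())
    return out


def _ckmeans_1d(values: np.ndarray, k: int) -> np.ndarray:
    """Exact 1-D k-means by dynamic programming (O(n²k)): the optimal
    partition into k contiguous-in-value clusters minimizing the
    within-cluster sum of squares."""
    order = np.argsort(values, kind="stable")
    x = values[order]
    n = x.size
    prefix = np.concatenate([[0.0], np.cumsum(x)])
    prefix2 = np.concatenate([[0.0], np.cumsum(x**2)])

    def sse(i: int, j: int) -> float:
        # within-cluster SS for x[i:j]
        s = prefix[j] - prefix[i]
        s2 = prefix2[j] - prefix2[i]
        return s2 - s * s / (j - i)

    cost = np.full((k + 1, n + 1), np.inf)
    split = np.zeros((k + 1, n + 1), dtype=int)
    cost[0, 0] = 0.0
    for c in range(1, k + 1):
        for j in range(c, n + 1):
            for i in range(c - 1, j):
                cand = cost[c - 1, i] + sse(i, j)
                if cand < cost[c, j] - 1e-15:
                    cost[c, j] = cand
                    split[c, j] = i
    labels_sorted = np.empty(n, dtype=int)
    j = n
    for c in range(k, 0, -1):
        i = split[c, j]
        labels_sorted[i:j] = c - 1
        j = i
    labels = np.empty(n, dtype=int)
    labels[order] = labels_sorted
    return labels


def cluster_tumor_ratios(values: np.ndarray, k: int = 3) -> np.ndarray:
    """Partition mean tumor ratios into k value-contiguous clusters.

    Exact 1-D k-means (dynamic programming).  Labels are 1..k ordered by
    ascending cluster mean: 1 = normal-region association, k = tumor-core
    association.  With fewer than k distinct values each distinct value
    forms its own cluster (with a warning).
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("no values to cluster")
    n_distinct = np.unique(values).size
    k_eff = min(k, n_distinct)
    if k_eff < k:
        warnings.warn(
            f"only {n_distinct} distinct values; forming {k_eff} clusters"
        )
    raw = _ckmeans_1d(values, k_eff)
    means = [values[raw == c].mean() for c in range(k_eff)]
    rank = {c: r + 1 for r, c in enumerate(np.argsort(means, kind="stable"))}
    return np.array([rank[c] for c in raw])


def tumor_ratio_summary(
    field: GradientField,
    scaffold: GridScaffold,
    labels: TumorLabels,
    profile: SpatialProfile,
    k: int = 3,
) -> pd.DataFrame:
    """Per-feature mean tumor ratio and tumor-ratio-cluster (TRC) label."""
    ratios = grid_tumor_ratio(scaffold, labels, profile)
    means = program_mean_tumor_ratio(field, ratios)
    feats = list(means)
    if not feats:
        return pd.DataFrame(columns=["feature", "mean_tumor_ratio", "trc"])
    trc = cluster_tumor_ratios(np.array([means[f] for f in feats]), k=k)
    return pd.DataFrame(
        {"feature": feats, "mean_tumor_ratio": [means[f] for f in feats], "trc": trc}
    )
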