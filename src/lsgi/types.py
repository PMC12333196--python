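"""Core domain types for local spatial gradient inference.

The central container is :class:`SpatialProfile`: N spatial units (cells or
spots) with 2-D coordinates and a non-negative N×K feature matrix.  Features
are either NMF cell loadings (``factor_loadings``) or raw gene counts
(``gene_counts``, the single-gene mode used for targeted panels such as
seqFISH).  Coordinates are used exactly as given — no rescaling or centering —
so every distance downstream is Euclidean in the input units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np


class FeatureKind(str, Enum):
    """What the columns of ``SpatialProfile.features`` mean."""

    factor_loadings = "factor_loadings"
    gene_counts = "gene_counts"


@dataclass
class SpatialProfile:
    """Spatial units with coordinates and a non-negative feature matrix.

    Parameters
    ----------
    unit_ids : list of str
        One identifier per unit; unique.
    coords : (N, 2) float array
        x, y positions in input units (arbitrary scale).
    features : (N, K) float array
        Non-negative NMF loadings or raw counts.
    feature_names : list of str
        K unique column names.
    feature_kind : FeatureKind
    """

    unit_ids: list[str]
    coords: np.ndarray
    features: np.ndarray
    feature_names: list[str]
    feature_kind: FeatureKind = FeatureKind.factor_loadings

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.features = np.asarray(self.features, dtype=float)
        self.unit_ids = [str(u) for u in self.unit_ids]
        self.feature_names = [str(f) for f in self.feature_names]
        if isinstance(self.feature_kind, str):
            self.feature_kind = FeatureKind(self.feature_kind)
        n = len(self.unit_ids)
        if n < 1:
            raise ValueError("SpatialProfile needs at least one unit")
        if self.coords.shape != (n, 2):
            raise ValueError(
                f"coords shape {self.coords.shape} does not match {n} units × 2"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords contain missing or non-finite values")
        if self.features.shape[0] != n:
            raise ValueError(
                f"features have {self.features.shape[0]} rows for {n} units"
            )
        if not np.all(np.isfinite(self.features)):
            raise ValueError("features contain missing or non-finite values")
        if np.any(self.features < 0):
            bad = np.argwhere(self.features < 0)[0]
            raise ValueError(
                f"features must be non-negative; first negative entry at "
                f"unit {self.unit_ids[bad[0]]}, feature "
                f"{self.feature_names[bad[1]]}"
            )
        if self.features.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length does not match feature columns")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature_names must be unique")
        if len(set(self.unit_ids)) != n:
            raise ValueError("unit_ids must be unique")

    @property
    def n_units(self) -> int:
        return len(self.unit_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)


@dataclass
class LsgiConfig:
    """Tunable parameters of the gradient-inference pipeline.

    ``s`` controls how many grid points tile the tissue (P = floor(N/S));
    ``q`` is the window size (Q nearest units to each grid point); windows
    with a joint-fit coefficient of determination at or above ``r2_cutoff``
    count as gradients, and a feature must show gradients in at least
    ``min_grid_frac`` of all grid points to be retained.
    """

    s: int = 5
    q: int = 25
    r2_cutoff: float = 0.6
    min_grid_frac: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.s < 1:
            raise ValueError("s must be a positive integer")
        if self.q < 1:
            raise ValueError("q must be a positive integer")
        if not 0.0 <= self.r2_cutoff <= 1.0:
            raise ValueError("r2_cutoff must lie in [0, 1]")
        if not 0.0 <= self.min_grid_frac <= 1.0:
            raise ValueError("min_grid_frac must lie in [0, 1]")
        if self.s > self.q:
            warnings.warn(
                f"s={self.s} exceeds q={self.q}; windows will not tile the "
                "tissue (each unit lands in fewer than one window on average)",
                stacklevel=2,
            )


@dataclass
class TumorLabels:
    """Per-unit tumor/normal annotation aligned to a SpatialProfile by id."""

    unit_ids: list[str]
    is_tumor: np.ndarray

    def __post_init__(self) -> None:
        self.unit_ids = [str(u) for u in self.unit_ids]
        self.is_tumor = np.asarray(self.is_tumor, dtype=bool)
        if len(self.unit_ids) != self.is_tumor.shape[0]:
            raise ValueError("one label required per unit id")
        if len(set(self.unit_ids)) != len(self.unit_ids):
            raise ValueError("duplicate unit ids in tumor labels")

    def aligned_to(self, profile: SpatialProfile) -> np.ndarray:
        """Boolean tumor mask in the profile's unit order.

        Raises if any profile unit lacks a label.
        """
        lookup = dict(zip(self.unit_ids, self.is_tumor))
        missing = [u for u in profile.unit_ids if u not in lookup]
        if missing:
            raise ValueError(
                f"tumor labels missing for {len(missing)} unit(s): "
                + ", ".join(missing[:10])
            )
        return np.array([lookup[u] for u in profile.unit_ids], dtype=bool)


@dataclass
class ProgramSignature:
    """Top-gene signature of one NMF program from one sample.

    Genes are ordered by descending loading; at most ``n`` (default 50) genes.
    ``category`` carries the (tumor_type, study) pair used for compositional
    entropy.
    """

    program_id: str
    genes: list[str]
    loadings: list[float] = field(default_factory=list)
    category: tuple[str, str] = ("", "")

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"duplicate genes in signature {self.program_id}")
        if self.loadings and len(self.loadings) != len(self.genes):
            raise ValueError("loadings must match genes one-to-one")
        if self.loadings:
            arr = np.asarray(self.loadings, dtype=float)
            if np.any(arr < 0):
                raise ValueError("loadings must be non-negative")
            if np.any(np.diff(arr) > 1e-12):
                raise ValueError("loadings must be sorted descending")

    @property
    def gene_set(self) -> frozenset:
        return frozenset(self.genes)


@dataclass
class MetaProgram:
    """A cluster of program signatures summarized by a merged 50-gene list."""

    mp_id: str
    members: list[str]
    signature: list[str]

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("a meta-program needs at least 2 members")
        if len(set(self.signature)) != len(self.signature):
            raise ValueError("meta-program signature genes must be unique")


def as_float_matrix(x: Sequence, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr
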