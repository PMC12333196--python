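"""Local gradient inference: per-window linear fits, filtering, directions.

For every grid window and every feature j the model F_j ~ x + y is fit by
ordinary least squares; the (unadjusted) coefficient of determination R²
measures how much of the feature's local variation is explained by position,
and the coefficient vector (β_x, β_y) points toward increasing feature value —
the local gradient direction.  Windows with R² at or above a cutoff (default
0.6; 0.3 is the recommended setting for sparse single-gene counts with Q=20)
count as gradients, and a feature is retained only if it shows gradients in at
least a fraction (default 5%) of all grid points.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .gridding import GridScaffold
from .types import LsgiConfig, SpatialProfile

FIT_COLUMNS = [
    "grid_id", "grid_x", "grid_y", "feature",
    "beta_x", "beta_y", "intercept", "r2", "dir_x", "dir_y",
]


@dataclass
class LocalFit:
    """One window × feature regression result."""

    grid_id: int
    feature: str
    beta_x: float
    beta_y: float
    intercept: float
    r2: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.r2 <= 1.0):
            raise ValueError(f"r2={self.r2} outside [0, 1]")
        for name in ("beta_x", "beta_y", "intercept"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} is not finite")


@dataclass
class GradientField:
    """All per-(grid, feature) fits plus the retained (filtered) subset.

    ``fits`` holds one row per grid × feature; ``retained`` is the subset
    with r2 ≥ r2_cutoff restricted to features passing the grid-fraction
    rule, whose names are listed in ``retained_features``.
    """

    fits: pd.DataFrame
    retained: pd.DataFrame
    retained_features: list[str]
    scaffold: GridScaffold
    r2_cutoff: float = 0.6
    min_grid_frac: float = 0.05
    feature_names: list[str] = field(default_factory=list)

    def retained_grid_coords(self, feature: str) -> np.ndarray:
        """Coordinates of the grid points where ``feature`` shows a gradient."""
        rows = self.retained[self.retained["feature"] == feature]
        return rows[["grid_x", "grid_y"]].to_numpy()

    @property
    def n_grids(self) -> int:
        return self.scaffold.p


def _ols_window(xy: np.ndarray, values: np.ndarray) -> tuple[np.ndarray, ...]:
    """OLS of each value column on (1, x, y).

    Returns (betas (K,2), intercepts (K,), r2 (K,)).  Constant columns get
    zero slopes and r2 = 0 by convention so downstream filtering never sees
    missing values; rank-deficient (collinear) windows are fit on the
    identifiable subspace via the minimum-norm least-squares solution.
    """
    xy = np.asarray(xy, dtype=float)
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    n = xy.shape[0]
    if n < 3:
        raise ValueError("a gradient window needs at least 3 points")
    if not (np.all(np.isfinite(xy)) and np.all(np.isfinite(values))):
        raise ValueError("non-finite inputs to local fit")

    design = np.column_stack([np.ones(n), xy])
    coefs, _, _, _ = np.linalg.lstsq(design, values, rcond=None)
    fitted = design @ coefs
    ss_res = ((values - fitted) ** 2).sum(axis=0)
    centered = values - values.mean(axis=0)
    ss_tot = (centered**2).sum(axis=0)

    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(ss_tot > 0, 1.0 - ss_res / np.where(ss_tot > 0, ss_tot, 1.0), 0.0)
    r2 = np.clip(r2, 0.0, 1.0)
    betas = coefs[1:3].T.copy()
    intercepts = coefs[0].copy()
    constant = ss_tot <= 0
    betas[constant] = 0.0
    intercepts[constant] = values[0, constant]
    return betas, intercepts, r2


def fit_local_gradient(
    coords_window: np.ndarray,
    values_window: np.ndarray,
    grid_id: int = 0,
    feature: str = "feature",
) -> LocalFit:
    """Fit one window: OLS of values on (1, x, y)."""
    betas, intercepts, r2 = _ols_window(coords_window, values_window)
    return LocalFit(
        grid_id=grid_id,
        feature=feature,
        beta_x=float(betas[0, 0]),
        beta_y=float(betas[0, 1]),
        intercept=float(intercepts[0]),
        r2=float(r2[0]),
    )


def gradient_direction(fit: LocalFit) -> np.ndarray | None:
    """Unit vector pointing toward increasing feature value, or None when
    both coefficients are exactly zero."""
    vec = np.array([fit.beta_x, fit.beta_y], dtype=float)
    norm = np.linalg.norm(vec)
    if norm == 0.0:
        return None
    return vec / norm


def min_grid_count(p: int, min_grid_frac: float) -> int:
    """Minimum number of gradient-bearing grid points for feature retention:
    max(1, floor(frac · P))."""
    if p < 1:
        raise ValueError("p must be >= 1")
    if not 0.0 <= min_grid_frac <= 1.0:
        raise ValueError("min_grid_frac must lie in [0, 1]")
    return max(1, int(math.floor(min_grid_frac * p)))


def infer_gradients(
    profile: SpatialProfile, scaffold: GridScaffold, config: LsgiConfig
) -> GradientField:
    """Fit every (grid, feature) pair and filter to salient gradients.

    Returns a GradientField with all P×K fits, the retained subset per
    ``config.r2_cutoff``, and the features passing the grid-fraction rule.
    Deterministic: no randomness enters the fits.
    """
    if scaffold.members and max(int(m.max()) for m in scaffold.members) >= profile.n_units:
        raise ValueError("scaffold refers to unit indices beyond the profile")

    k = profile.n_features
    p = scaffold.p
    beta_all = np.empty((p, k, 2))
    inter_all = np.empty((p, k))
    r2_all = np.empty((p, k))
    for gi, members in enumerate(scaffold.members):
        xy = profile.coords[members]
        vals = profile.features[members]
        beta_all[gi], inter_all[gi], r2_all[gi] = _ols_window(xy, vals)

    grid_ids = np.repeat(np.arange(p), k)
    feats = np.tile(np.asarray(profile.feature_names, dtype=object), p)
    bx = beta_all[:, :, 0].ravel()
    by = beta_all[:, :, 1].ravel()
    norms = np.hypot(bx, by)
    with np.errstate(divide="ignore", invalid="ignore"):
        dir_x = np.where(norms > 0, bx / np.where(norms > 0, norms, 1.0), np.nan)
        dir_y = np.where(norms > 0, by / np.where(norms > 0, norms, 1.0), np.nan)

    fits = pd.DataFrame(
        {
            "grid_id": grid_ids,
            "grid_x": np.repeat(scaffold.grid_coords[:, 0], k),
            "grid_y": np.repeat(scaffold.grid_coords[:, 1], k),
            "feature": feats,
            "beta_x": bx,
            "beta_y": by,
            "intercept": inter_all.ravel(),
            "r2": r2_all.ravel(),
            "dir_x": dir_x,
            "dir_y": dir_y,
        }
    )
    raw = GradientField(
        fits=fits,
        retained=fits.iloc[0:0],
        retained_features=[],
        scaffold=scaffold,
        r2_cutoff=config.r2_cutoff,
        min_grid_frac=config.min_grid_frac,
        feature_names=list(profile.feature_names),
    )
    return filter_gradients(raw, config.r2_cutoff, config.min_grid_frac)


def filter_gradients(
    field: GradientField, r2_cutoff: float, min_grid_frac: float
) -> GradientField:
    """Apply the R² cutoff and the minimum-grid-fraction retention rule.

    ``retained`` keeps fits with r2 ≥ cutoff whose feature shows gradients in
    at least max(1, floor(min_grid_frac · P)) grid points.
    """
    passing = field.fits[field.fits["r2"] >= r2_cutoff]
    threshold = min_grid_count(field.scaffold.p, min_grid_frac)
    counts = passing.groupby("feature", sort=False)["grid_id"].nunique()
    kept_features = [f for f, c in counts.items() if c >= threshold]
    retained = passing[passing["feature"].isin(kept_features)].reset_index(drop=True)
    return replace(
        field,
        retained=retained,
        retained_features=kept_features,
        r2_cutoff=r2_cutoff,
        min_grid_frac=min_grid_frac,
    )
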