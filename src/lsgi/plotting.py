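"""Arrow-map and heatmap visualization of inferred gradients.

The canonical view places one arrow per retained (grid, feature) pair at the
grid coordinate, oriented toward increasing feature value.  Arrow length is
constant by default — direction and color carry the information — with an
option to scale by R².  Tumor-annotated units are overlaid as gray circles.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .gradients import GradientField
from .relations import GradientDistanceMatrix
from .types import SpatialProfile, TumorLabels


@dataclass
class PlotSpec:
    """Options for the gradient arrow map."""

    color_by: str = "feature"          # "feature" or "loading"
    loading_feature: str | None = None  # feature to color spots by
    tumor_overlay: bool = True
    arrow_scale: float = 1.0
    scale_by_r2: bool = False
    output: str | Path = "gradient_map.png"

    def __post_init__(self) -> None:
        if self.arrow_scale <= 0:
            raise ValueError("arrow_scale must be positive")
        if self.color_by not in ("feature", "loading"):
            raise ValueError("color_by must be 'feature' or 'loading'")


def plot_gradient_map(
    profile: SpatialProfile,
    field: GradientField,
    labels: TumorLabels | None = None,
    spec: PlotSpec | None = None,
) -> Path:
    """Write the arrow map; returns the output path.

    One arrow per retained (grid, feature) fit; an empty retained set yields
    a spot map with zero arrows.  Inputs are never modified.
    """
    spec = spec or PlotSpec()
    fig, ax = plt.subplots(figsize=(7, 6))

    if spec.color_by == "loading":
        feat = spec.loading_feature or (
            field.retained_features[0] if field.retained_features else None
        )
        if feat is None:
            raise ValueError("color_by='loading' needs a feature to color by")
        values = profile.features[:, profile.feature_names.index(feat)]
        sc = ax.scatter(
            profile.coords[:, 0], profile.coords[:, 1],
            c=values, s=12, cmap="viridis", linewidths=0,
        )
        fig.colorbar(sc, ax=ax, label=f"{feat} loading")
    else:
        ax.scatter(
            profile.coords[:, 0], profile.coords[:, 1],
            c="lightgray", s=12, linewidths=0,
        )

    if labels is not None and spec.tumor_overlay:
        mask = labels.aligned_to(profile)
        ax.scatter(
            profile.coords[mask, 0], profile.coords[mask, 1],
            facecolors="none", edgecolors="dimgray", s=28, linewidths=0.8,
            label="tumor",
        )

    retained = field.retained
    if len(retained):
        span = np.ptp(profile.coords, axis=0).max() or 1.0
        base = 0.02 * span * spec.arrow_scale
        feats = list(dict.fromkeys(retained["feature"]))
        cmap = plt.get_cmap("tab10")
        colors = {f: cmap(i % 10) for i, f in enumerate(feats)}
        for row in retained.itertuples():
            if not np.isfinite(row.dir_x):
                continue
            length = base * (row.r2 if spec.scale_by_r2 else 1.0)
            ax.annotate(
                "",
                xy=(row.grid_x + row.dir_x * length,
                    row.grid_y + row.dir_y * length),
                xytext=(row.grid_x, row.grid_y),
                arrowprops=dict(
                    arrowstyle="-|>", color=colors[row.feature], lw=1.2
                ),
            )
        handles = [
            plt.Line2D([0], [0], color=colors[f], lw=2, label=f) for f in feats
        ]
        ax.legend(handles=handles, fontsize=7, loc="upper right",
                  title="gradient")

    ax.set_xlabel("x")
    ax.set_ylabel("y")
    ax.set_aspect("equal")
    ax.set_title(f"{len(retained)} local gradients "
                 f"(R² ≥ {field.r2_cutoff:g})")
    out = Path(spec.output)
    fig.savefig(out, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return out


def plot_distance_heatmap(
    matrix: GradientDistanceMatrix, output: str | Path
) -> Path:
    """Log-scaled heatmap of the directed gradient distance matrix
    (row = from, column = to)."""
    logd = matrix.log_transformed()
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(logd.to_numpy(), cmap="magma")
    ax.set_xticks(range(len(matrix.features)))
    ax.set_yticks(range(len(matrix.features)))
    ax.set_xticklabels(matrix.features, rotation=90, fontsize=7)
    ax.set_yticklabels(matrix.features, fontsize=7)
    fig.colorbar(im, ax=ax, label="ln(distance + ε)")
    ax.set_title("directed gradient distance (from row to column)")
    out = Path(output)
    fig.savefig(out, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return out
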