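"""Readers and writers for the package's external formats.

Coordinates are TSV/CSV with columns ``id,x,y``.  Feature matrices are either
dense TSV/CSV (units × features, header row, first column = unit id) or
MatrixMarket triplets with sidecar row/column name files.  Gene sets use GMT.
All joins are exact, case-sensitive string matches on ids, so reader output is
invariant to the row order of the input files.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import yaml

from .types import FeatureKind, LsgiConfig, ProgramSignature, SpatialProfile, TumorLabels

logger = logging.getLogger("lsgi")


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_coordinates(path: str | Path) -> pd.DataFrame:
    """Read an ``id,x,y`` table; returns a DataFrame indexed by string id."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype={0: str})
    cols = [c.lower() for c in df.columns]
    for required in ("id", "x", "y"):
        if required not in cols:
            raise ValueError(f"{path}: missing required column '{required}'")
    df.columns = cols
    df = df[["id", "x", "y"]]
    for axis in ("x", "y"):
        coerced = pd.to_numeric(df[axis], errors="coerce")
        if coerced.isna().any():
            bad = df.loc[coerced.isna(), "id"].iloc[0]
            raise ValueError(f"{path}: non-numeric {axis} coordinate for id {bad!r}")
        df[axis] = coerced.astype(float)
    return df.set_index("id")


def _read_features_dense(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    df.index = df.index.astype(str)
    return df.astype(float)


def _read_features_mtx(path: Path) -> pd.DataFrame:
    mat = scipy.io.mmread(path)
    if scipy.sparse.issparse(mat):
        mat = mat.toarray()
    rows_file = path.with_suffix(".rows.txt")
    cols_file = path.with_suffix(".cols.txt")
    for f in (rows_file, cols_file):
        if not f.exists():
            raise FileNotFoundError(
                f"MTX sidecar name file not found: {f} (expected next to {path})"
            )
    row_names = rows_file.read_text().split()
    col_names = cols_file.read_text().split()
    if len(row_names) != mat.shape[0] or len(col_names) != mat.shape[1]:
        raise ValueError(
            f"{path}: sidecar names ({len(row_names)}×{len(col_names)}) do not "
            f"match matrix shape {mat.shape}"
        )
    return pd.DataFrame(np.asarray(mat, dtype=float), index=row_names, columns=col_names)


def read_spatial_profile(
    coords_path: str | Path,
    features_path: str | Path,
    feature_kind: FeatureKind | str = FeatureKind.factor_loadings,
) -> SpatialProfile:
    """Load and align coordinates and features into a validated profile.

    Feature rows are realigned to the coordinate file's unit order by id;
    ids present in one file but not the other raise an alignment error
    naming the offending ids.
    """
    coords = read_coordinates(coords_path)
    features_path = Path(features_path)
    if features_path.suffix.lower() == ".mtx":
        feats = _read_features_mtx(features_path)
    else:
        feats = _read_features_dense(features_path)

    coord_ids = set(coords.index)
    feat_ids = set(feats.index)
    if coord_ids != feat_ids:
        only_coords = sorted(coord_ids - feat_ids)
        only_feats = sorted(feat_ids - coord_ids)
        parts = []
        if only_coords:
            parts.append(f"ids only in coordinates: {only_coords[:10]}")
        if only_feats:
            parts.append(f"ids only in features: {only_feats[:10]}")
        raise ValueError("id mismatch between files; " + "; ".join(parts))

    feats = feats.loc[coords.index]
    return SpatialProfile(
        unit_ids=list(coords.index),
        coords=coords[["x", "y"]].to_numpy(),
        features=feats.to_numpy(),
        feature_names=list(feats.columns),
        feature_kind=FeatureKind(feature_kind),
    )


def read_tumor_labels(path: str | Path) -> TumorLabels:
    """Read a TSV/CSV with columns ``id`` and ``is_tumor`` (bool/0/1)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype={0: str})
    df.columns = [c.lower() for c in df.columns]
    if "id" not in df.columns or "is_tumor" not in df.columns:
        raise ValueError(f"{path}: requires columns 'id' and 'is_tumor'")
    truthy = {"true": True, "false": False, "1": True, "0": False}
    labels = [
        truthy[str(v).strip().lower()] if str(v).strip().lower() in truthy else bool(v)
        for v in df["is_tumor"]
    ]
    return TumorLabels(unit_ids=list(df["id"]), is_tumor=np.array(labels))


def read_gene_sets(gmt_path: str | Path) -> dict[str, list[str]]:
    """Parse a GMT file into ``{set name: gene list}``.

    Duplicate genes within a set are dropped, keeping first occurrence;
    set order follows the file.
    """
    sets: dict[str, list[str]] = {}
    with open(gmt_path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{gmt_path}:{lineno}: GMT line needs name, description and "
                    f"at least one gene (got {len(fields)} fields)"
                )
            name = fields[0]
            genes = list(dict.fromkeys(g for g in fields[2:] if g))
            sets[name] = genes
    return sets


# ---------------------------------------------------------------------------
# gradient tables

GRADIENT_COLUMNS = [
    "grid_id", "grid_x", "grid_y", "feature",
    "beta_x", "beta_y", "intercept", "r2", "dir_x", "dir_y",
]


def write_gradient_table(fits: pd.DataFrame, path: str | Path) -> None:
    """Write fit rows as TSV, sorted by (grid_id, feature); 12 sig digits."""
    df = fits.copy()
    for col in GRADIENT_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"gradient table missing column {col!r}")
    df = df[GRADIENT_COLUMNS].sort_values(["grid_id", "feature"], kind="mergesort")
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_gradient_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"feature": str})
    missing = [c for c in GRADIENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing gradient columns {missing}")
    return df


# ---------------------------------------------------------------------------
# program signatures

def read_signatures(path: str | Path) -> list[ProgramSignature]:
    """Read a signature table (program_id, gene, loading, tumor_type, study).

    Rows for one program must be ordered by descending loading; genes beyond
    the top 50 per program are truncated.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    df.columns = [c.lower() for c in df.columns]
    needed = {"program_id", "gene", "loading"}
    if not needed <= set(df.columns):
        raise ValueError(f"{path}: requires columns {sorted(needed)}")
    out = []
    for pid, grp in df.groupby("program_id", sort=False):
        grp = grp.assign(loading=grp["loading"].astype(float))
        grp = grp.sort_values("loading", ascending=False, kind="mergesort").head(50)
        cat = (
            str(grp["tumor_type"].iloc[0]) if "tumor_type" in grp.columns else "",
            str(grp["study"].iloc[0]) if "study" in grp.columns else "",
        )
        out.append(
            ProgramSignature(
                program_id=str(pid),
                genes=list(grp["gene"]),
                loadings=list(grp["loading"]),
                category=cat,
            )
        )
    return out


def write_signatures(signatures: list[ProgramSignature], path: str | Path) -> None:
    rows = []
    for sig in signatures:
        loadings = sig.loadings or [float("nan")] * len(sig.genes)
        for gene, loading in zip(sig.genes, loadings):
            rows.append(
                {
                    "program_id": sig.program_id,
                    "gene": gene,
                    "loading": loading,
                    "tumor_type": sig.category[0],
                    "study": sig.category[1],
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# configuration & logging

def read_config(path: str | Path) -> LsgiConfig:
    """Load an LsgiConfig from a YAML mapping; absent keys keep defaults."""
    with open(path) as handle:
        data = yaml.safe_load(handle) or {}
    allowed = {"s", "q", "r2_cutoff", "min_grid_frac", "seed"}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    return LsgiConfig(**data)


def write_config(config: LsgiConfig, path: str | Path) -> None:
    payload = {
        "s": config.s,
        "q": config.q,
        "r2_cutoff": config.r2_cutoff,
        "min_grid_frac": config.min_grid_frac,
        "seed": config.seed,
    }
    with open(path, "w") as handle:
        yaml.safe_dump(payload, handle, sort_keys=False)


def configure_logging(verbose: bool = False) -> None:
    level = logging.DEBUG if verbose else logging.INFO
    logging.basicConfig(
        level=level, format="%(asctime)s %(name)s %(levelname)s %(message)s"
    )
    logger.setLevel(level)
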