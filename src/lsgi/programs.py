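"""Cross-sample meta-analysis of gradient-bearing NMF programs.

Per-sample programs are summarized by their top-50 gene signatures and merged
into meta-programs by a founder-based agglomeration: the program with the most
high-overlap partners (>20 of 50 genes shared, at least two such partners)
seeds a cluster that greedily absorbs the best-overlapping remaining program
(≥20 genes vs. the current merged signature), re-deriving the 50-gene
signature after every merge.  Compositional (Shannon) entropy against a
label-permutation null quantifies whether a meta-program is tumor-type- or
study-specific, and hypergeometric enrichment with a cross-program
specificity score annotates it functionally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .types import MetaProgram, ProgramSignature

FOUNDER_OVERLAP = 20   # strict >, partners needed to seed a cluster
GROWTH_OVERLAP = 20    # inclusive ≥, to merge into a growing cluster


def program_overlap(a: ProgramSignature, b: ProgramSignature) -> int:
    """Number of shared genes between two signatures."""
    return len(a.gene_set & b.gene_set)


def meta_signature(members: list[ProgramSignature], n: int = 50) -> list[str]:
    """Merged signature of a cluster of programs.

    Genes are ranked by (i) the number of member programs whose top list
    contains the gene, descending; (ii) the gene's mean within-program rank
    (1 = highest loading), ascending; (iii) gene name.  The top ``n`` genes
    are returned; if fewer distinct genes exist across members, all are
    returned with a warning.
    """
    if len(members) < 2:
        raise ValueError("meta_signature needs at least 2 member programs")
    counts: dict[str, int] = {}
    rank_sums: dict[str, float] = {}
    for sig in members:
        for pos, gene in enumerate(sig.genes, start=1):
            counts[gene] = counts.get(gene, 0) + 1
            rank_sums[gene] = rank_sums.get(gene, 0.0) + pos
    ranked = sorted(
        counts,
        key=lambda g: (-counts[g], rank_sums[g] / counts[g], g),
    )
    if len(ranked) < n:
        warnings.warn(
            f"only {len(ranked)} distinct genes across members; "
            f"signature shorter than {n}"
        )
    return ranked[:n]


def _find_founder(
    sigs: dict[str, ProgramSignature],
    founder_overlap: int,
    min_partners: int,
) -> str | None:
    """Program with the most partners sharing > founder_overlap genes,
    requiring at least min_partners; ties broken by program id."""
    best_id, best_count = None, 0
    for pid in sorted(sigs):
        partners = sum(
            1
            for other in sigs
            if other != pid
            and program_overlap(sigs[pid], sigs[other]) > founder_overlap
        )
        if partners >= min_partners and partners > best_count:
            best_id, best_count = pid, partners
    return best_id


def cluster_meta_programs(
    signatures: list[ProgramSignature],
    founder_overlap: int = FOUNDER_OVERLAP,
    growth_overlap: int = GROWTH_OVERLAP,
    min_partners: int = 2,
    signature_size: int = 50,
) -> tuple[list[MetaProgram], list[str]]:
    """Founder-based agglomeration of program signatures into meta-programs.

    Returns (meta_programs, unclustered_program_ids).  Deterministic: all
    ties break by ascending program id, and cluster ids number the clusters
    in discovery order.
    """
    if not signatures:
        return [], []
    sigs = {s.program_id: s for s in signatures}
    if len(sigs) != len(signatures):
        raise ValueError("duplicate program ids")
    remaining = dict(sigs)
    metas: list[MetaProgram] = []
    while True:
        founder = _find_founder(remaining, founder_overlap, min_partners)
        if founder is None:
            break
        members = [founder]
        current = list(remaining[founder].genes)
        del remaining[founder]
        while True:
            current_set = set(current)
            best_id, best_ov = None, growth_overlap - 1
            for pid in sorted(remaining):
                ov = len(current_set & remaining[pid].gene_set)
                if ov > best_ov:
                    best_id, best_ov = pid, ov
            if best_id is None:
                break
            members.append(best_id)
            del remaining[best_id]
            current = meta_signature(
                [sigs[m] for m in members], n=signature_size
            )
        metas.append(
            MetaProgram(
                mp_id=f"MP_{len(metas) + 1}",
                members=members,
                signature=current,
            )
        )
    return metas, sorted(remaining)


# ---------------------------------------------------------------------------
# compositional entropy


@dataclass
class CompositionEntropy:
    """Observed vs. label-permutation entropy of a meta-program's makeup.

    ``delta = shuffled_mean − real_entropy`` by default, so that larger
    values indicate a more category-specific (lower-entropy) composition.
    """

    mp_id: str
    real_entropy: float
    shuffled_mean: float
    delta: float


def shannon_entropy(fractions: np.ndarray) -> float:
    """−Σ p ln p in nats, with 0·ln 0 ≡ 0."""
    p = np.asarray(fractions, dtype=float)
    if np.any(p < 0):
        raise ValueError("fractions must be non-negative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"fractions sum to {p.sum()}, not 1")
    nz = p[p > 0]
    return float(max(0.0, -(nz * np.log(nz)).sum()))


def _composition_entropy(labels: list[str]) -> float:
    _, counts = np.unique(np.asarray(labels, dtype=object), return_counts=True)
    return shannon_entropy(counts / counts.sum())


def delta_shannon(
    mp_members: list[str],
    all_labels: dict[str, str],
    n_shuffles: int = 10,
    seed: int = 0,
    mp_id: str = "",
    flip_sign: bool = False,
) -> CompositionEntropy:
    """Delta-Shannon entropy of a meta-program's category composition.

    The observed entropy of the members' category makeup is compared with
    the mean entropy under ``n_shuffles`` global permutations of category
    labels across all programs in the pool.  ``delta`` is shuffled_mean −
    real (larger = more specific); ``flip_sign=True`` reports real −
    shuffled_mean instead.
    """
    missing = [m for m in mp_members if m not in all_labels]
    if missing:
        raise ValueError(f"unlabeled member programs: {missing[:5]}")
    pool_ids = list(all_labels)
    pool_labels = np.asarray([all_labels[p] for p in pool_ids], dtype=object)
    member_pos = np.asarray([pool_ids.index(m) for m in mp_members])
    real = _composition_entropy([all_labels[m] for m in mp_members])

    rng = np.random.default_rng(seed)
    sims = np.empty(n_shuffles)
    for i in range(n_shuffles):
        perm = rng.permutation(pool_labels)
        sims[i] = _composition_entropy(list(perm[member_pos]))
    shuffled_mean = float(sims.mean())
    delta = real - shuffled_mean if flip_sign else shuffled_mean - real
    return CompositionEntropy(
        mp_id=mp_id, real_entropy=real, shuffled_mean=shuffled_mean, delta=delta
    )


# ---------------------------------------------------------------------------
# hypergeometric annotation


def hypergeom_enrichment(
    query: list[str],
    gene_sets: dict[str, list[str]],
    universe: list[str],
    log_base: float = 10.0,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of each gene set in a query.

    For each set, p = P(overlap ≥ observed) drawing |query| genes from a
    |universe|-gene pool containing |set ∩ universe| set genes.  p-values
    are Benjamini–Hochberg adjusted across sets, and E = −log(adjusted p)
    in the given base.
    """
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("empty universe")
    query_set = set(query)
    if not query_set:
        raise ValueError("empty query")
    outside = query_set - universe_set
    if outside:
        raise ValueError(
            f"query genes outside the universe: {sorted(outside)[:5]}"
        )
    m = len(universe_set)
    n_query = len(query_set)
    rows = []
    for name, genes in gene_sets.items():
        in_universe = set(genes) & universe_set
        overlap = len(in_universe & query_set)
        p = float(hypergeom.sf(overlap - 1, m, len(in_universe), n_query))
        p = min(max(p, np.finfo(float).tiny), 1.0)
        rows.append({"gene_set": name, "overlap": overlap, "p": p})
    df = pd.DataFrame(rows)
    df["adj_p"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    df["E"] = -np.log(df["adj_p"]) / np.log(log_base)
    return df


def enrichment_table(
    queries: dict[str, list[str]],
    gene_sets: dict[str, list[str]],
    universe: list[str],
    log_base: float = 10.0,
) -> pd.DataFrame:
    """Enrichment of every gene set in every program/meta-program query,
    with the cross-program specificity score attached.

    BH adjustment is applied within each program across gene sets.
    """
    parts = []
    for program, genes in queries.items():
        part = hypergeom_enrichment(genes, gene_sets, universe, log_base)
        part.insert(0, "program", program)
        parts.append(part)
    table = pd.concat(parts, ignore_index=True)
    e = table.pivot(index="gene_set", columns="program", values="E")
    spec = specificity_score(e.to_numpy())
    spec_df = pd.DataFrame(spec, index=e.index, columns=e.columns)
    table["specificity"] = [
        spec_df.at[r.gene_set, r.program] for r in table.itertuples()
    ]
    return table


def specificity_score(e: np.ndarray) -> np.ndarray:
    """Per (set, program): E minus the mean E of the same set over the other
    programs.  Positive = more enriched here than elsewhere."""
    e = np.asarray(e, dtype=float)
    n = e.shape[1]
    if n < 2:
        raise ValueError("specificity needs at least 2 programs")
    totals = e.sum(axis=1, keepdims=True)
    return e - (totals - e) / (n - 1)


def annotate_meta_program(
    table: pd.DataFrame,
    mp_id: str,
    top_by_p: int = 40,
    top_by_specificity: int = 5,
) -> pd.DataFrame:
    """Reduce one meta-program's enrichment results to its annotation terms.

    Keep the ``top_by_p`` sets with smallest adjusted p, then the
    ``top_by_specificity`` of those with highest cross-program specificity,
    ordered by specificity descending.  Returns fewer rows when fewer sets
    survive.
    """
    sub = table[table["program"] == mp_id]
    if sub.empty:
        raise ValueError(f"no enrichment rows for {mp_id!r}")
    shortlist = sub.nsmallest(top_by_p, "adj_p", keep="first")
    top = shortlist.sort_values(
        ["specificity", "gene_set"], ascending=[False, True], kind="mergesort"
    ).head(top_by_specificity)
    return top.reset_index(drop=True)
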