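"""Coexpression module discovery, scoring, and age testing.

Modules are found on the spot x gene matrix of posterior mean expression
(lambda): the gene-gene Pearson correlation matrix feeds a KNN graph
(k = 10 most-correlated neighbors, undirected union, negative weights
floored at 0) clustered with Leiden at resolution 2; modules under 50
genes are discarded. Cell-type submodules re-cluster each module's genes
on depth-normalized (10k), log1p-transformed single-nucleus expression
(k = 10, resolution 1). Per-spot module scores clip each member gene at
its 99th percentile, z-scale across spots, and average members; age
differences are tested on per-(array, AAR) mean scores with Welch's t
and Benjamini-Hochberg correction across the whole family.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datasets import counts_matrix

logger = logging.getLogger(__name__)

#: Welch/BH significance tiers (q-value cutoffs).
Q_TIERS = (0.05, 1e-2, 1e-3, 1e-4)


@dataclass
class ModulePartition:
    """Gene -> module assignment (and optional module -> submodule map)."""

    module_of_gene: dict[str, int]
    unassigned: list[str] = field(default_factory=list)
    submodule_of_gene: dict[str, str] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    @property
    def module_sizes(self) -> dict[int, int]:
        sizes: dict[int, int] = {}
        for m in self.module_of_gene.values():
            sizes[m] = sizes.get(m, 0) + 1
        return sizes

    def members(self, module: int) -> list[str]:
        return [g for g, m in self.module_of_gene.items() if m == module]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "gene": g,
                "module": m,
                "submodule": self.submodule_of_gene.get(g, ""),
            }
            for g, m in self.module_of_gene.items()
        ]
        return pd.DataFrame(rows)


def gene_correlation(lambda_matrix: pd.DataFrame) -> pd.DataFrame:
    """Gene-gene Pearson correlation across spots.

    Zero-variance genes get correlation 0 against all others (logged).
    """
    X = lambda_matrix.to_numpy(dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 spots to correlate genes")
    if not np.all(np.isfinite(X)):
        raise ValueError("expression matrix must be finite")
    sd = X.std(axis=0)
    flat = sd == 0
    if flat.any():
        logger.info("gene_correlation: %d zero-variance genes set to r=0", flat.sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    corr[flat, :] = 0.0
    corr[:, flat] = 0.0
    np.fill_diagonal(corr, 1.0)
    corr = np.clip(corr, -1.0, 1.0)
    return pd.DataFrame(corr, index=lambda_matrix.columns, columns=lambda_matrix.columns)


def _knn_leiden(corr: np.ndarray, k: int, resolution: float, seed: int) -> np.ndarray:
    """Leiden membership on the undirected union KNN graph of a correlation."""
    n = corr.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be < number of genes ({n})")
    c = corr.copy()
    np.fill_diagonal(c, -np.inf)
    nbrs = np.argsort(-c, axis=1, kind="stable")[:, :k]
    pairs = set()
    for i in range(n):
        for j in nbrs[i]:
            pairs.add((min(i, int(j)), max(i, int(j))))
    edges = sorted(pairs)
    weights = [max(float(corr[i, j]), 0.0) for i, j in edges]
    graph = ig.Graph(n=n, edges=edges)
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        weights=weights,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=2,
    )
    return np.asarray(part.membership)


def graph_cluster(
    corr: pd.DataFrame,
    k: int = 10,
    resolution: float = 2.0,
    min_size: int = 50,
    seed: int = 0,
) -> ModulePartition:
    """KNN + Leiden modules on a gene correlation matrix.

    Modules smaller than ``min_size`` are dropped and their genes marked
    unassigned. Module ids are renumbered by decreasing size.
    """
    genes = list(corr.index)
    membership = _knn_leiden(corr.to_numpy(dtype=float), k, resolution, seed)
    labels, counts = np.unique(membership, return_counts=True)
    kept = labels[counts >= min_size]
    order = kept[np.argsort(-counts[np.isin(labels, kept)], kind="stable")]
    renumber = {int(old): new for new, old in enumerate(order)}
    module_of_gene, unassigned = {}, []
    for g, m in zip(genes, membership):
        if int(m) in renumber:
            module_of_gene[g] = renumber[int(m)]
        else:
            unassigned.append(g)
    return ModulePartition(
        module_of_gene=module_of_gene,
        unassigned=unassigned,
        provenance={"k": k, "resolution": resolution, "min_size": min_size, "seed": seed},
    )


def normalize_log1p(counts: np.ndarray, target: float = 1e4) -> np.ndarray:
    """Depth-normalize rows to ``target`` counts, then log1p."""
    depth = counts.sum(axis=1, keepdims=True)
    depth[depth == 0] = 1.0
    return np.log1p(counts / depth * target)


def derive_submodules(
    partition: ModulePartition,
    nuclei: AnnData,
    k: int = 10,
    resolution: float = 1.0,
    seed: int = 0,
) -> ModulePartition:
    """Cell-type submodules of each module from matched nuclei.

    Nuclei counts are depth-normalized to 10k and log1p-transformed;
    each module's member genes are re-correlated over nuclei and
    re-clustered (no minimum size). Submodule ids are "M<i>.<j>".
    """
    norm = normalize_log1p(counts_matrix(nuclei))
    gene_pos = {g: i for i, g in enumerate(nuclei.var_names)}
    sub: dict[str, str] = {}
    for m in sorted(set(partition.module_of_gene.values())):
        members = partition.members(m)
        present = [g for g in members if g in gene_pos]
        absent = set(members) - set(present)
        if absent:
            logger.info(
                "derive_submodules: module %d: %d genes absent from nuclei data",
                m,
                len(absent),
            )
        if not present:
            continue
        if len(present) == 1:
            sub[present[0]] = f"M{m}.0"
            continue
        X = norm[:, [gene_pos[g] for g in present]]
        corr = gene_correlation(pd.DataFrame(X, columns=present))
        membership = _knn_leiden(
            corr.to_numpy(), min(k, len(present) - 1), resolution, seed
        )
        for g, s in zip(present, membership):
            sub[g] = f"M{m}.{int(s)}"
    return ModulePartition(
        module_of_gene=dict(partition.module_of_gene),
        unassigned=list(partition.unassigned),
        submodule_of_gene=sub,
        provenance={**partition.provenance, "sub_k": k, "sub_resolution": resolution},
    )


def clipped_zscores(
    values: np.ndarray, clip_q: float = 0.99
) -> np.ndarray:
    """Clip each column at its ``clip_q`` quantile (linear interpolation),
    then z-scale across rows; constant columns map to 0 (logged)."""
    X = values.astype(float).copy()
    hi = np.quantile(X, clip_q, axis=0)
    X = np.minimum(X, hi)
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    flat = sd == 0
    if flat.any():
        logger.info("clipped_zscores: %d constant genes contribute 0", int(flat.sum()))
    sd[flat] = 1.0
    Z = (X - mean) / sd
    Z[:, flat] = 0.0
    return Z


def score_module_spots(
    lambda_matrix: pd.DataFrame,
    member_genes,
    spot_meta: pd.DataFrame | None = None,
    clip_q: float = 0.99,
) -> pd.DataFrame:
    """Per-spot module score: mean of clipped, z-scaled member genes.

    If ``spot_meta`` (with ``array_id``, ``aar``, and optionally
    ``donor_id``/``age_group``) is given, the result carries those
    columns for aggregation.
    """
    missing = [g for g in member_genes if g not in lambda_matrix.columns]
    if missing:
        raise KeyError(f"member genes absent from expression matrix: {missing[:5]}")
    Z = clipped_zscores(lambda_matrix[list(member_genes)].to_numpy(), clip_q)
    out = pd.DataFrame({"score": Z.mean(axis=1)}, index=lambda_matrix.index)
    if spot_meta is not None:
        for col in ("array_id", "donor_id", "age_group", "aar"):
            if col in spot_meta.columns:
                out[col] = spot_meta[col].to_numpy()
    return out


def aggregate_scores(scores: pd.DataFrame, by=("array_id", "aar")) -> pd.DataFrame:
    """Mean score per grouping (e.g. per array and AAR): batch estimates."""
    keep = [c for c in ("age_group", "donor_id") if c in scores.columns and c not in by]
    agg = (
        scores.groupby(list(by), observed=True)
        .agg(score=("score", "mean"), **{c: (c, "first") for c in keep})
        .reset_index()
    )
    return agg


def test_scores_by_age(
    score_tables: dict[str, pd.DataFrame],
    comparisons=(("old", "young"), ("middle", "young"), ("old", "middle")),
) -> pd.DataFrame:
    """Welch's t on per-(array, AAR) module scores, BH across the family.

    ``score_tables`` maps module name -> per-spot score table (from
    :func:`score_module_spots` with metadata). Groups with fewer than 2
    arrays are skipped and recorded with a NaN p-value.
    """
    rows = []
    for module, scores in score_tables.items():
        agg = aggregate_scores(scores)
        for aar in sorted(agg["aar"].unique()):
            sub = agg[agg["aar"] == aar]
            for ga, gb in comparisons:
                a = sub.loc[sub["age_group"] == ga, "score"].to_numpy()
                b = sub.loc[sub["age_group"] == gb, "score"].to_numpy()
                row = {
                    "module": module,
                    "aar": aar,
                    "comparison": f"{ga}_vs_{gb}",
                    "n_a": len(a),
                    "n_b": len(b),
                }
                if len(a) < 2 or len(b) < 2:
                    row.update(t=np.nan, p=np.nan, skipped=True)
                    logger.info(
                        "test_scores_by_age: skipped %s/%s %s_vs_%s (<2 arrays)",
                        module, aar, ga, gb,
                    )
                elif np.ptp(np.concatenate([a, b])) == 0:
                    row.update(t=0.0, p=1.0, skipped=False)
                else:
                    t, p = stats.ttest_ind(a, b, equal_var=False)
                    row.update(t=float(t), p=float(p), skipped=False)
                row["delta"] = (
                    float(a.mean() - b.mean()) if len(a) and len(b) else np.nan
                )
                rows.append(row)
    table = pd.DataFrame(rows)
    mask = table["p"].notna()
    table["q"] = np.nan
    if mask.any():
        table.loc[mask, "q"] = multipletests(table.loc[mask, "p"], method="fdr_bh")[1]
    table["tier"] = sum((table["q"] < c).astype(int) for c in Q_TIERS)
    return table
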