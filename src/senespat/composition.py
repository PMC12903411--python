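"""Marker derivation, least-squares deconvolution, and composition testing.

Markers are derived from per-(cell type, donor) pseudobulk: types need at
least 10 cells in at least two donors; pseudo-samples are depth-normalized
to 1e4 and log-transformed; genes pass with > 1.25 mean log-fold change
versus other types and BH-adjusted p < 0.05 (Wilcoxon rank-sum across
pseudo-samples), the global top 1% by dispersion (variance/mean within
each type, averaged over types) are discarded, and lists are balanced by
truncation to the smallest surviving count.

Deconvolution here is a plain non-negative least-squares fit of each
spot's marker expression onto per-type mean marker profiles — deliberate
plumbing standing in for external probabilistic deconvolution tools —
with weights normalized to sum to 1 per spot. Composition-vs-age testing
uses donor-by-layer mean compositions with the Wilcoxon rank-sum test and
Benjamini-Hochberg correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .coexpression import normalize_log1p
from .datasets import counts_matrix

logger = logging.getLogger(__name__)


@dataclass
class MarkerSet:
    """Balanced marker genes per cell type, with dispersion scores."""

    markers: dict[str, list[str]]
    dispersion: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))

    @property
    def all_genes(self) -> list[str]:
        out = []
        for genes in self.markers.values():
            out.extend(genes)
        return out

    def validate(self) -> None:
        counts = {t: len(g) for t, g in self.markers.items()}
        if len(set(counts.values())) > 1:
            raise ValueError(f"marker lists not balanced: {counts}")
        allg = self.all_genes
        if len(allg) != len(set(allg)):
            raise ValueError("a gene appears in two types' marker lists")


def pseudobulk(
    nuclei: AnnData, min_cells: int = 10, min_donors: int = 2
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-(cell type, donor) pseudo-samples, normalized to 1e4 and log1p.

    Types without at least ``min_cells`` cells in at least ``min_donors``
    donors are dropped. Returns (pseudo-sample x gene matrix, metadata
    with cell_type and donor_id per pseudo-sample).
    """
    obs = nuclei.obs
    X = counts_matrix(nuclei)
    rows, meta = [], []
    for t in sorted(obs["broad_class"].unique()):
        t_mask = (obs["broad_class"] == t).to_numpy()
        per_donor = obs.loc[t_mask, "donor_id"].value_counts()
        if (per_donor >= min_cells).sum() < min_donors:
            logger.info("pseudobulk: dropping %s (10-cells/2-donors rule)", t)
            continue
        for donor in per_donor.index[per_donor >= min_cells]:
            sel = t_mask & (obs["donor_id"] == donor).to_numpy()
            rows.append(X[sel].sum(axis=0))
            meta.append({"cell_type": t, "donor_id": donor})
    if not rows:
        raise ValueError("no cell types satisfy the 10-cells/2-donors rule")
    mat = normalize_log1p(np.vstack(rows), target=1e4)
    return (
        pd.DataFrame(mat, columns=nuclei.var_names),
        pd.DataFrame(meta),
    )


def select_markers(
    pseudo: pd.DataFrame,
    pseudo_meta: pd.DataFrame,
    lfc_min: float = 1.25,
    padj_max: float = 0.05,
    dispersion_drop: float = 0.01,
) -> MarkerSet:
    """Balanced marker genes per cell type from pseudo-samples.

    Per type, genes are rank-tested (Wilcoxon rank-sum, BH) against all
    other types' pseudo-samples and gated at mean logFC > ``lfc_min``
    and q < ``padj_max``; the global top ``dispersion_drop`` fraction by
    dispersion is discarded; each type's list is truncated to the
    minimum surviving count (ties broken by logFC). A gene passing in
    several types is assigned to the type where its logFC is largest.
    """
    types = sorted(pseudo_meta["cell_type"].unique())
    if len(types) < 2:
        raise ValueError("need at least 2 cell types to derive markers")
    X = pseudo.to_numpy()
    genes = pseudo.columns

    # dispersion: variance/mean within each type, averaged across types
    disp = np.zeros(X.shape[1])
    for t in types:
        sub = X[(pseudo_meta["cell_type"] == t).to_numpy()]
        mean = sub.mean(axis=0)
        var = sub.var(axis=0, ddof=1) if len(sub) > 1 else np.zeros(X.shape[1])
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(mean > 0, var / mean, 0.0)
        disp += r / len(types)
    n_drop = int(np.floor(dispersion_drop * X.shape[1]))
    high_disp = set(np.argsort(-disp, kind="stable")[:n_drop]) if n_drop else set()

    candidates: dict[int, tuple[str, float, float]] = {}
    per_type: dict[str, list[tuple[float, float, int]]] = {t: [] for t in types}
    for t in types:
        mask = (pseudo_meta["cell_type"] == t).to_numpy()
        a, b = X[mask], X[~mask]
        lfc = a.mean(axis=0) - b.mean(axis=0)
        p = _ranksum_p(X, mask)
        q = multipletests(p, method="fdr_bh")[1]
        passing = np.flatnonzero((lfc > lfc_min) & (q < padj_max))
        for j in passing:
            if j in high_disp:
                continue
            prev = candidates.get(j)
            if prev is None or lfc[j] > prev[1]:
                candidates[j] = (t, float(lfc[j]), float(q[j]))
    for j, (t, lfc_j, q_j) in candidates.items():
        per_type[t].append((q_j, -lfc_j, j))
    empty = [t for t in types if not per_type[t]]
    if empty:
        raise ValueError(f"no surviving markers for cell type(s): {empty}")
    n_keep = min(len(v) for v in per_type.values())
    markers = {
        t: [str(genes[j]) for _, _, j in sorted(per_type[t])[:n_keep]] for t in types
    }
    ms = MarkerSet(markers=markers, dispersion=pd.Series(disp, index=genes))
    ms.validate()
    return ms


def _ranksum_p(X: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Two-sided Wilcoxon rank-sum p per column (normal approx, tie-corrected)."""
    n = X.shape[0]
    na = int(mask.sum())
    nb = n - na
    ranks = stats.rankdata(X, axis=0)
    U = ranks[mask].sum(axis=0) - na * (na + 1) / 2.0
    mean = na * nb / 2.0
    # tie correction per column
    tie_term = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        _, counts = np.unique(X[:, j], return_counts=True)
        tie_term[j] = np.sum(counts**3 - counts)
    var = na * nb / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    p = np.ones(X.shape[1])
    ok = var > 0
    z = (np.abs(U[ok] - mean) - 0.5) / np.sqrt(var[ok])
    p[ok] = 2 * stats.norm.sf(np.maximum(z, 0.0))
    return np.minimum(p, 1.0)


def reference_profiles(
    pseudo: pd.DataFrame, pseudo_meta: pd.DataFrame, markers: MarkerSet
) -> pd.DataFrame:
    """Per-type mean pseudo-sample expression over the marker genes."""
    cols = markers.all_genes
    rows = {}
    for t in markers.markers:
        mask = (pseudo_meta["cell_type"] == t).to_numpy()
        rows[t] = pseudo.loc[mask, cols].mean(axis=0).to_numpy()
    return pd.DataFrame(rows, index=cols).T


def deconvolve_nnls(
    spatial: AnnData, reference: pd.DataFrame, use_normalized: bool = True
) -> pd.DataFrame:
    """Non-negative least-squares composition per spot.

    Observed marker expression (depth-normalized, log1p by default) is
    fitted as a non-negative combination of the per-type reference
    profiles; weights are normalized to sum to 1. All-zero spots receive
    a uniform composition and are flagged in the ``degenerate`` column.
    """
    genes = [g for g in reference.columns if g in spatial.var_names]
    if not genes:
        raise ValueError("no reference marker genes present in the spatial data")
    ref = reference[genes].to_numpy()
    X = counts_matrix(spatial[:, genes])
    if use_normalized:
        full = counts_matrix(spatial)
        depth = full.sum(axis=1, keepdims=True)
        depth[depth == 0] = 1.0
        X = np.log1p(X / depth * 1e4)
    A = ref.T  # (genes, types)
    comps = np.zeros((X.shape[0], ref.shape[0]))
    degenerate = np.zeros(X.shape[0], dtype=bool)
    for s in range(X.shape[0]):
        if not X[s].any():
            comps[s] = 1.0 / ref.shape[0]
            degenerate[s] = True
            continue
        w, _ = optimize.nnls(A, X[s])
        if w.sum() == 0:
            comps[s] = 1.0 / ref.shape[0]
            degenerate[s] = True
        else:
            comps[s] = w / w.sum()
    out = pd.DataFrame(comps, columns=reference.index, index=spatial.obs_names)
    out["degenerate"] = degenerate
    return out


def test_composition_age(
    compositions: pd.DataFrame,
    spot_meta: pd.DataFrame,
    comparisons=(("old", "young"), ("middle", "young"), ("old", "middle")),
    min_donors: int = 2,
) -> pd.DataFrame:
    """Wilcoxon rank-sum on donor-by-layer mean compositions, BH family.

    ``compositions`` is the per-spot output of :func:`deconvolve_nnls`;
    ``spot_meta`` must carry ``donor_id``, ``age_group``, ``aar``.
    Strata with fewer than ``min_donors`` donors per group are skipped
    and recorded with NaN. Exact p-values at small n.
    """
    types = [c for c in compositions.columns if c != "degenerate"]
    df = compositions[types].copy()
    for col in ("donor_id", "age_group", "aar"):
        df[col] = spot_meta[col].to_numpy()
    donor_layer = (
        df.groupby(["donor_id", "aar"], observed=True)
        .agg({**{t: "mean" for t in types}, "age_group": "first"})
        .reset_index()
    )
    rows = []
    for t in types:
        for aar in sorted(donor_layer["aar"].unique()):
            sub = donor_layer[donor_layer["aar"] == aar]
            for ga, gb in comparisons:
                a = sub.loc[sub["age_group"] == ga, t].to_numpy()
                b = sub.loc[sub["age_group"] == gb, t].to_numpy()
                row = {
                    "cell_type": t,
                    "aar": aar,
                    "comparison": f"{ga}_vs_{gb}",
                    "n_a": len(a),
                    "n_b": len(b),
                    "delta": float(a.mean() - b.mean()) if len(a) and len(b) else np.nan,
                }
                if len(a) < min_donors or len(b) < min_donors:
                    row.update(u=np.nan, p=np.nan, skipped=True)
                    logger.info(
                        "test_composition_age: skipped %s/%s %s_vs_%s",
                        t, aar, ga, gb,
                    )
                elif np.ptp(np.concatenate([a, b])) == 0:
                    row.update(u=float(len(a) * len(b) / 2), p=1.0, skipped=False)
                else:
                    res = stats.mannwhitneyu(
                        a, b, alternative="two-sided",
                        method="exact" if max(len(a), len(b)) <= 8 else "asymptotic",
                    )
                    row.update(u=float(res.statistic), p=float(res.pvalue),
                               skipped=False)
                rows.append(row)
    table = pd.DataFrame(rows)
    mask = table["p"].notna()
    table["q"] = np.nan
    if mask.any():
        table.loc[mask, "q"] = multipletests(table.loc[mask, "p"], method="fdr_bh")[1]
    return table
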