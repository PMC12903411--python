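"""Decile labeling of spot scores and permutation neighborhood enrichment.

Each spot is scored for a gene set (mean normalized expression of the
set minus a fixed random control set of 2,000 non-member genes), then
assigned a decile label 1..10 from the score distribution over all
spots pooled across age groups. For a group of spots, the enrichment of
decile pair (i, j) is the z-score of the observed count of adjacent
spot pairs with labels {i, j} against a null built by permuting labels
independently within each array (1,000 permutations by default, sample
standard deviation). An exact mode enumerates every within-array label
arrangement when the total is small.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import permutations as _perms
from math import factorial

import numpy as np
import pandas as pd
from anndata import AnnData

from .coexpression import normalize_log1p
from .datasets import counts_matrix
from .spatial_model import SpotGraph

logger = logging.getLogger(__name__)

N_DECILES = 10


@dataclass
class EnrichmentMatrix:
    """Pairwise decile enrichment for one (gene set, group)."""

    z: np.ndarray  # (10, 10)
    observed: np.ndarray
    perm_mean: np.ndarray
    perm_sd: np.ndarray
    degenerate: np.ndarray  # True where sd == 0 (z undefined)
    n_perm: int


def score_spots(
    spatial: AnnData, gene_set, control_n: int = 2000, seed: int = 0
) -> np.ndarray:
    """Per-spot module score: mean(set) - mean(random non-member controls).

    Controls are drawn once (seeded) from genes outside ``gene_set``;
    when fewer than ``control_n`` are available all are used (logged).
    Expression is depth-normalized to 10k and log1p-transformed.
    """
    gene_set = list(gene_set)
    if not gene_set:
        raise ValueError("empty gene set")
    missing = [g for g in gene_set if g not in spatial.var_names]
    if missing:
        raise KeyError(f"gene set members absent: {missing[:5]}")
    norm = normalize_log1p(counts_matrix(spatial))
    var_index = {g: i for i, g in enumerate(spatial.var_names)}
    set_idx = [var_index[g] for g in gene_set]
    pool = np.array([i for g, i in var_index.items() if g not in set(gene_set)])
    rng = np.random.default_rng(np.random.SeedSequence([seed, 31]))
    if len(pool) < control_n:
        logger.info(
            "score_spots: control pool has %d genes (< %d); using all",
            len(pool), control_n,
        )
        ctrl_idx = pool
    else:
        ctrl_idx = rng.choice(pool, size=control_n, replace=False)
    return norm[:, set_idx].mean(axis=1) - norm[:, np.sort(ctrl_idx)].mean(axis=1)


def assign_deciles(scores: np.ndarray) -> tuple[np.ndarray, dict]:
    """Decile labels 1..10 over all spots pooled.

    Spots are ranked by (score, stable position) and split into ten
    equal-count blocks, so each label's share is 10% up to remainder
    spots; the implied cut points are the empirical decile quantiles.
    Constant scores yield all-1 labels with a degeneracy flag.
    """
    scores = np.asarray(scores, dtype=float)
    n = len(scores)
    if n < N_DECILES:
        raise ValueError("need at least 10 spots to assign deciles")
    info: dict = {"degenerate": False}
    if np.ptp(scores) == 0:
        info["degenerate"] = True
        logger.info("assign_deciles: constant scores; all spots labeled 1")
        return np.ones(n, dtype=int), info
    order = np.argsort(scores, kind="stable")
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(n)
    labels = (ranks * N_DECILES) // n + 1
    info["cut_points"] = np.quantile(scores, np.arange(1, N_DECILES) / N_DECILES)
    return labels.astype(int), info


def _pair_counts(labels: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Symmetric 10x10 unordered pair counts over edges."""
    O = np.zeros((N_DECILES, N_DECILES))
    if len(edges):
        li = labels[edges[:, 0]] - 1
        lj = labels[edges[:, 1]] - 1
        np.add.at(O, (li, lj), 1.0)
        np.add.at(O, (lj, li), 1.0)
    # each unordered pair counted once; diagonal counted once per edge
    O = np.triu(O) + np.triu(O, 1).T
    np.fill_diagonal(O, np.diag(O) / 2.0)
    return O


def pairwise_enrichment(
    labels: np.ndarray,
    graph: SpotGraph,
    group_mask: np.ndarray | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    method: str = "permutation",
) -> EnrichmentMatrix:
    """Permutation z-scores for adjacency of decile pairs.

    The null permutes labels independently within each array (arrays as
    batches), preserving each array's label multiset. ``method="exact"``
    enumerates all distinct within-array label arrangements (only
    feasible for tiny inputs). Pairs never observed under the null get
    sd = 0 and are flagged degenerate rather than given a z-score.
    """
    labels = np.asarray(labels, dtype=int)
    if group_mask is None:
        group_mask = np.ones(graph.n_spots, dtype=bool)
    group_mask = np.asarray(group_mask, dtype=bool)
    if not group_mask.any():
        raise ValueError("empty spot group")
    idx = np.flatnonzero(group_mask)
    remap = -np.ones(graph.n_spots, dtype=int)
    remap[idx] = np.arange(len(idx))
    e = graph.edges
    keep = group_mask[e[:, 0]] & group_mask[e[:, 1]]
    edges = remap[e[keep]]
    sub_labels = labels[idx]
    arrays = np.asarray(graph.array_of_spot)[idx]

    observed = _pair_counts(sub_labels, edges)
    array_ids = pd.unique(arrays)
    masks = [np.flatnonzero(arrays == a) for a in array_ids]

    if method == "exact":
        perms = _exact_permutations(sub_labels, masks)
        counts = np.stack([_pair_counts(p, edges) for p in perms])
        n_used = len(perms)
    elif method == "permutation":
        rng = np.random.default_rng(np.random.SeedSequence([seed, 37]))
        counts = np.empty((n_perm, N_DECILES, N_DECILES))
        perm = sub_labels.copy()
        for it in range(n_perm):
            for m in masks:
                perm[m] = rng.permutation(perm[m])
            counts[it] = _pair_counts(perm, edges)
        n_used = n_perm
    else:
        raise ValueError(f"unknown method {method!r}")

    mean = counts.mean(axis=0)
    sd = counts.std(axis=0, ddof=1) if n_used > 1 else np.zeros_like(mean)
    degenerate = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (observed - mean) / sd
    z[degenerate] = np.nan
    if degenerate.all():
        logger.info("pairwise_enrichment: permutation-invariant labels; z undefined")
    return EnrichmentMatrix(
        z=z, observed=observed, perm_mean=mean, perm_sd=sd,
        degenerate=degenerate, n_perm=n_used,
    )


def _exact_permutations(labels: np.ndarray, masks) -> list[np.ndarray]:
    """All distinct label arrangements, permuting within each array."""
    total = 1
    per_array: list[list[tuple]] = []
    for m in masks:
        opts = sorted(set(_perms(labels[m].tolist())))
        per_array.append(opts)
        total *= len(opts)
        if total > 20000:
            raise ValueError("exact enumeration infeasible; use method='permutation'")
    out = []

    def rec(i, current):
        if i == len(masks):
            out.append(current.copy())
            return
        for opt in per_array[i]:
            current[masks[i]] = opt
            rec(i + 1, current)

    rec(0, labels.astype(int).copy())
    return out
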