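"""Senescence hallmark scoring, positivity classification, and CDKN2A analyses.

A nucleus's module score for a hallmark gene set is the mean normalized
expression of the set genes minus the mean of expression-bin-matched
control genes drawn from one fixed control set (nominally 2,000 genes in
no hallmark list), the control-feature scheme of single-cell module
scoring. Positivity thresholds are the 95th percentile of young-group
scores, computed separately per broad class and hallmark; a nucleus is
positive when its score strictly exceeds the threshold, and "3+
hallmarks" means positivity for at least three of the seven individual
hallmark programs. CDKN2A (p16) positivity is transcript count > 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import stats

from .coexpression import normalize_log1p
from .datasets import counts_matrix
from .genesets import HallmarkGeneSets, INDIVIDUAL_HALLMARKS
from .nuclei_stats import masc_test

logger = logging.getLogger(__name__)

MIN_YOUNG_STRATUM = 20


def nuclei_module_score(
    nuclei: AnnData,
    gene_set,
    control_set,
    n_bins: int = 24,
    n_ctrl_per_gene: int = 100,
    seed: int = 0,
    normalized: np.ndarray | None = None,
) -> np.ndarray:
    """Control-matched module score per nucleus.

    Expression is depth-normalized to 10k and log1p-transformed. All
    genes are binned (``n_bins`` equal-frequency bins) by their mean
    normalized expression; for each set gene up to ``n_ctrl_per_gene``
    controls are sampled (seeded) from its bin within the fixed control
    set, falling back to the whole control set for empty bins (logged).
    The score is mean(set genes) - mean(sampled controls).
    """
    gene_set = [g for g in gene_set]
    control_set = list(control_set)
    overlap = set(gene_set) & set(control_set)
    if overlap:
        raise ValueError(f"control set overlaps the gene set: {sorted(overlap)[:5]}")
    missing = [g for g in gene_set if g not in nuclei.var_names]
    if missing:
        raise KeyError(f"gene set members absent: {missing[:5]}")
    norm = normalize_log1p(counts_matrix(nuclei)) if normalized is None else normalized
    var_index = {g: i for i, g in enumerate(nuclei.var_names)}

    avg = norm.mean(axis=0)
    order = np.argsort(avg, kind="stable")
    bin_of_gene = np.empty(len(avg), dtype=int)
    bin_of_gene[order] = np.minimum(
        (np.arange(len(avg)) * n_bins) // len(avg), n_bins - 1
    )

    ctrl_idx = np.array([var_index[g] for g in control_set if g in var_index])
    rng = np.random.default_rng(np.random.SeedSequence([seed, 23]))
    chosen: list[int] = []
    for g in gene_set:
        gi = var_index[g]
        pool = ctrl_idx[bin_of_gene[ctrl_idx] == bin_of_gene[gi]]
        if len(pool) == 0:
            logger.info(
                "nuclei_module_score: empty control bin for %s; whole-pool fallback", g
            )
            pool = ctrl_idx
        take = min(n_ctrl_per_gene, len(pool))
        chosen.extend(rng.choice(pool, size=take, replace=False).tolist())
    set_idx = [var_index[g] for g in gene_set]
    return norm[:, set_idx].mean(axis=1) - norm[:, sorted(set(chosen))].mean(axis=1)


def score_all_hallmarks(
    nuclei: AnnData, hgs: HallmarkGeneSets, n_bins: int = 24, seed: int = 0
) -> pd.DataFrame:
    """Per-nucleus score for every hallmark list, one column per hallmark."""
    hgs.validate()
    norm = normalize_log1p(counts_matrix(nuclei))
    present = set(nuclei.var_names)
    out = {}
    for name, genes in hgs.all_lists.items():
        usable = [g for g in genes if g in present]
        out[name] = nuclei_module_score(
            nuclei,
            usable,
            [g for g in hgs.control_set if g in present],
            n_bins=n_bins,
            seed=seed,
            normalized=norm,
        )
    return pd.DataFrame(out, index=nuclei.obs_names)


def positivity_thresholds(
    scores: pd.DataFrame,
    young_mask,
    broad_class,
    q: float = 0.95,
    min_young: int = MIN_YOUNG_STRATUM,
) -> pd.DataFrame:
    """Young-referenced thresholds per (broad class, hallmark).

    The threshold is the ``q`` quantile (linear interpolation) of
    young-group scores within each broad class, separately per hallmark.
    Strata with fewer than ``min_young`` young nuclei get NaN (positivity
    downstream is then missing).
    """
    young_mask = np.asarray(young_mask, dtype=bool)
    broad_class = np.asarray(broad_class)
    rows = []
    for cls in pd.unique(broad_class):
        stratum = young_mask & (broad_class == cls)
        for hallmark in scores.columns:
            vals = scores.loc[stratum, hallmark].to_numpy()
            thr = np.quantile(vals, q) if len(vals) >= min_young else np.nan
            if len(vals) < min_young:
                logger.info(
                    "positivity_thresholds: %s/%s has %d young nuclei (<%d)",
                    cls, hallmark, len(vals), min_young,
                )
            rows.append(
                {"broad_class": cls, "hallmark": hallmark, "threshold": thr,
                 "n_young": int(stratum.sum())}
            )
    return pd.DataFrame(rows)


def classify_positive(
    scores: pd.DataFrame, thresholds: pd.DataFrame, broad_class
) -> pd.DataFrame:
    """Boolean positivity per (nucleus, hallmark) plus the 3+ hallmark flag.

    Positivity is strict (score > threshold); the multi-hallmark count is
    over the seven individual hallmark programs only. Missing thresholds
    yield missing positivity (excluded from the count).
    """
    broad_class = np.asarray(broad_class)
    thr_map = {
        (r["broad_class"], r["hallmark"]): r["threshold"]
        for _, r in thresholds.iterrows()
    }
    out = pd.DataFrame(index=scores.index)
    for hallmark in scores.columns:
        thr = np.array([thr_map.get((c, hallmark), np.nan) for c in broad_class])
        vals = scores[hallmark].to_numpy()
        pos = pd.array(vals > thr, dtype="boolean")
        pos[np.isnan(thr)] = pd.NA
        out[hallmark] = pos
    individual = [h for h in INDIVIDUAL_HALLMARKS if h in scores.columns]
    counts = out[individual].fillna(False).astype(bool).sum(axis=1)
    out["n_individual_positive"] = counts
    out["multi_hallmark"] = counts >= 3
    return out


def cdkn2a_positivity(
    nuclei: AnnData, gene: str = "CDKN2A", cell_class: str | None = "Oli"
) -> tuple[pd.DataFrame, dict]:
    """Per-donor p16+ fraction (transcript count > 0) and its age trend.

    Restricts to ``cell_class`` nuclei when given; donors without nuclei
    of the class are excluded (logged). Returns the per-donor table and
    the OLS regression of positivity percentage on age of death.
    """
    if gene not in nuclei.var_names:
        raise KeyError(f"{gene} not present in the dataset")
    mask = (
        (nuclei.obs["broad_class"] == cell_class).to_numpy()
        if cell_class is not None
        else np.ones(nuclei.n_obs, dtype=bool)
    )
    counts = counts_matrix(nuclei[:, gene]).ravel()
    obs = nuclei.obs
    rows = []
    for donor in obs["donor_id"].unique():
        sel = mask & (obs["donor_id"] == donor).to_numpy()
        if sel.sum() == 0:
            logger.info("cdkn2a_positivity: donor %s has no %s nuclei", donor, cell_class)
            continue
        rows.append(
            {
                "donor_id": donor,
                "age": float(obs.loc[sel, "age"].iloc[0]),
                "age_group": obs.loc[sel, "age_group"].iloc[0],
                "n_nuclei": int(sel.sum()),
                "pct_positive": 100.0 * float((counts[sel] > 0).mean()),
            }
        )
    table = pd.DataFrame(rows)
    if len(table) >= 3 and table["age"].nunique() > 1:
        fit = stats.linregress(table["age"], table["pct_positive"])
        trend = {
            "slope": float(fit.slope),
            "intercept": float(fit.intercept),
            "p": float(fit.pvalue),
            "r2": float(fit.rvalue**2),
            "stderr": float(fit.stderr),
        }
    else:
        trend = {"slope": np.nan, "intercept": np.nan, "p": np.nan, "r2": np.nan,
                 "stderr": np.nan}
    return table, trend


def proportion_difference_stat(
    positive, group_mask_a, group_mask_b
) -> tuple[float, float]:
    """One-sided two-proportion z statistic (a > b) for heatmap display."""
    pos = np.asarray(positive, dtype=float)
    a = np.asarray(group_mask_a, dtype=bool)
    b = np.asarray(group_mask_b, dtype=bool)
    na, nb = a.sum(), b.sum()
    if na == 0 or nb == 0:
        return 0.0, 1.0
    pa, pb = pos[a].mean(), pos[b].mean()
    pool = pos[a | b].mean()
    denom = pool * (1 - pool) * (1 / na + 1 / nb)
    if denom == 0:
        return 0.0, 1.0
    z = (pa - pb) / np.sqrt(denom)
    return float(z), float(stats.norm.sf(z))


def test_positivity_by_age(
    positivity: pd.DataFrame,
    nuclei: AnnData,
    comparisons=(("old", "young"), ("middle", "young")),
    hallmarks=None,
) -> pd.DataFrame:
    """Mixed-effects test of positivity rates per (broad class, hallmark).

    Delegates to :func:`senespat.nuclei_stats.masc_test` with sex fixed
    and batch as the random effect (the senescence configuration), and
    additionally reports a one-sided difference-of-proportions statistic
    for display. Strata where the MASC model cannot run (e.g. a class
    absent in one group) are recorded with NaN.
    """
    obs = nuclei.obs
    hallmarks = list(hallmarks or [h for h in INDIVIDUAL_HALLMARKS if h in positivity])
    rows = []
    for cls in sorted(obs["broad_class"].unique()):
        cls_mask = (obs["broad_class"] == cls).to_numpy()
        sub = nuclei[cls_mask]
        for hallmark in hallmarks:
            pos = positivity.loc[cls_mask, hallmark]
            known = pos.notna().to_numpy()
            for ga, gb in comparisons:
                row = {
                    "broad_class": cls,
                    "hallmark": hallmark,
                    "comparison": f"{ga}_vs_{gb}",
                }
                grp = sub.obs["age_group"].to_numpy()
                in_cmp = np.isin(grp, [ga, gb]) & known
                posv = pos.fillna(False).to_numpy(dtype=bool)
                if in_cmp.sum() == 0 or posv[in_cmp].sum() in (0, in_cmp.sum()):
                    # no informative variation in this stratum
                    res = None
                else:
                    try:
                        res = masc_test(
                            sub[known],
                            posv[known],
                            comparison=(ga, gb),
                            random_effects=("batch",),
                        )
                    except Exception as exc:  # degenerate stratum
                        logger.info(
                            "test_positivity_by_age: %s/%s %s failed: %s",
                            cls, hallmark, f"{ga}_vs_{gb}", exc,
                        )
                        res = None
                z, pz = proportion_difference_stat(
                    posv, (grp == ga) & known, (grp == gb) & known
                )
                if res is None:
                    row.update(odds_ratio=np.nan, p=1.0 if in_cmp.sum() else np.nan,
                               separated=False)
                else:
                    row.update(
                        odds_ratio=res.odds_ratio, p=res.p, separated=res.separated
                    )
                row.update(z_proportion=z, p_proportion=pz)
                rows.append(row)
    return pd.DataFrame(rows)
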