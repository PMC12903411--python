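"""Single-nucleus statistics: MASC composition tests, pseudobulk DE, ROC markers.

``masc_test`` is a mixed-effects logistic regression of per-nucleus
cluster membership on age group (fixed) and sex (fixed) with random
intercepts for donor and/or batch (donors nested in batches), the
MASC design. The marginal likelihood integrates the random effects by
Gauss-Hermite quadrature; the age effect is tested by a likelihood-ratio
test and reported as an odds ratio with a Wald 95% CI.

``pseudobulk_de`` is a deliberately simple pseudobulk linear model:
per-donor summed counts on log2 CPM regressed on age in years (plus sex
and batch), with Benjamini-Hochberg correction. No precision weights
are used; heteroscedasticity is handled only through pseudobulking.

``auc_rank_markers`` ranks genes by the area under the ROC curve of
expression as a classifier of group membership (rank-based, ties
mid-ranked), as used for p16+ marker discovery.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .datasets import counts_matrix
from .simulate import AGE_GROUP_MIDPOINTS

_GH_NODES = 12


@dataclass
class CompositionResult:
    """Mixed-effects logistic composition test for one cluster."""

    cluster: str
    comparison: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float
    n_units: int
    separated: bool = False
    sigma_donor: float = 0.0
    sigma_batch: float = 0.0


@lru_cache(maxsize=1)
def _gh_points():
    t, w = np.polynomial.hermite.hermgauss(_GH_NODES)
    return np.sqrt(2.0) * t, np.log(w / np.sqrt(np.pi))


def _masc_nll(params, X, y, n, donor_batch, n_fixed, use_donor, use_batch):
    """Negative marginal log-likelihood of the nested binomial GLMM.

    Donor effects integrate out unit-wise (inner quadrature); batch
    effects couple the units of a batch (outer quadrature). Fully
    vectorized over a (units, donor nodes, batch nodes) grid.
    """
    beta = params[:n_fixed]
    i = n_fixed
    sd_d = np.exp(params[i]) if use_donor else 0.0
    i += int(use_donor)
    sd_b = np.exp(params[i]) if use_batch else 0.0
    lin = X @ beta
    nodes, log_w = _gh_points()

    d_nodes = sd_d * nodes if use_donor else np.zeros(1)
    b_nodes = sd_b * nodes if use_batch else np.zeros(1)
    d_logw = log_w if use_donor else np.zeros(1)
    b_logw = log_w if use_batch else np.zeros(1)

    # eta: (units, donor nodes, batch nodes)
    eta = lin[:, None, None] + d_nodes[None, :, None] + b_nodes[None, None, :]
    p = _expit_clip(eta)
    ll = y[:, None, None] * np.log(p) + (n - y)[:, None, None] * np.log1p(-p)
    unit_ll = _lse(ll + d_logw[None, :, None], axis=1)  # (units, batch nodes)
    batch_ll = np.stack([unit_ll[rows].sum(axis=0) for rows in donor_batch])
    total = float(_lse(batch_ll + b_logw[None, :], axis=1).sum())
    # weak half-normal(0, 3) regularization on the RE scales
    if use_donor:
        total -= 0.5 * (sd_d / 3.0) ** 2
    if use_batch:
        total -= 0.5 * (sd_b / 3.0) ** 2
    return -total


def _lse(a: np.ndarray, axis: int) -> np.ndarray:
    m = a.max(axis=axis, keepdims=True)
    return (m + np.log(np.exp(a - m).sum(axis=axis, keepdims=True))).squeeze(axis)


def _expit_clip(x):
    return np.clip(0.5 * (1.0 + np.tanh(0.5 * x)), 1e-12, 1.0 - 1e-12)


def _fit_masc(X, y, n, donor_batch, use_donor, use_batch):
    n_fixed = X.shape[1]
    x0 = np.zeros(n_fixed + int(use_donor) + int(use_batch))
    x0[n_fixed:] = np.log(0.3)
    rate = (y.sum() + 0.5) / (n.sum() + 1.0)
    x0[0] = np.log(rate / (1 - rate))
    batch_rows = [np.flatnonzero(donor_batch == b) for b in pd.unique(donor_batch)]
    args = (X, y, n, batch_rows, n_fixed, use_donor, use_batch)
    res = optimize.minimize(
        _masc_nll, x0, args=args, method="Nelder-Mead",
        options={"maxiter": 3000, "xatol": 1e-5, "fatol": 1e-7},
    )
    return res


def masc_test(
    nuclei: AnnData,
    cluster_label,
    comparison: tuple[str, str] = ("old", "young"),
    random_effects: tuple[str, ...] = ("donor_id", "batch"),
    include_sex: bool = True,
) -> CompositionResult:
    """MASC-style mixed-effects logistic test of cluster abundance.

    ``cluster_label`` is an obs column name or a boolean array marking
    cluster membership per nucleus. The fixed effect of interest is
    membership in ``comparison[0]`` vs ``comparison[1]``; sex is a fixed
    covariate, donor and batch random intercepts per ``random_effects``.
    Complete separation is reported with an infinite-OR flag.
    """
    obs = nuclei.obs
    member = (
        obs[cluster_label].to_numpy(dtype=bool)
        if isinstance(cluster_label, str)
        else np.asarray(cluster_label, dtype=bool)
    )
    ga, gb = comparison
    in_cmp = obs["age_group"].isin([ga, gb]).to_numpy()
    df = pd.DataFrame(
        {
            "donor": obs["donor_id"].to_numpy()[in_cmp],
            "batch": obs["batch"].to_numpy()[in_cmp],
            "sex": obs["sex"].to_numpy()[in_cmp],
            "is_a": (obs["age_group"].to_numpy()[in_cmp] == ga),
            "member": member[in_cmp],
        }
    )
    units = (
        df.groupby(["donor", "batch", "sex", "is_a"], observed=True)["member"]
        .agg(["sum", "count"])
        .reset_index()
    )
    y = units["sum"].to_numpy(dtype=float)
    n = units["count"].to_numpy(dtype=float)
    cols = [np.ones(len(units)), units["is_a"].to_numpy(dtype=float)]
    if include_sex and units["sex"].nunique() > 1:
        cols.append((units["sex"] == "F").to_numpy(dtype=float))
    X = np.column_stack(cols)
    use_donor = "donor_id" in random_effects
    use_batch = "batch" in random_effects
    donor_batch = units["batch"].to_numpy()

    full = _fit_masc(X, y, n, donor_batch, use_donor, use_batch)
    X0 = np.delete(X, 1, axis=1)
    null = _fit_masc(X0, y, n, donor_batch, use_donor, use_batch)
    lr = max(0.0, 2.0 * (null.fun - full.fun))
    p = float(stats.chi2.sf(lr, df=1))

    beta_age = float(full.x[1])
    a_arm = units["is_a"].to_numpy(dtype=bool)
    no_var = y[a_arm].sum() in (0.0, n[a_arm].sum()) or y[~a_arm].sum() in (
        0.0,
        n[~a_arm].sum(),
    )
    separated = abs(beta_age) > 12 or no_var
    batch_rows = [np.flatnonzero(donor_batch == b) for b in pd.unique(donor_batch)]
    se = _wald_se(full.x, 1, X, y, n, batch_rows, X.shape[1], use_donor, use_batch)
    if separated:
        or_, lo, hi = (np.inf if beta_age > 0 else 0.0), 0.0, np.inf
    else:
        or_ = float(np.exp(beta_age))
        if np.isfinite(se):
            lo = float(np.exp(beta_age - 1.96 * se))
            hi = float(np.exp(beta_age + 1.96 * se))
        else:
            lo, hi = 0.0, np.inf
    n_fixed = X.shape[1]
    i = n_fixed
    sd_d = float(np.exp(full.x[i])) if use_donor else 0.0
    sd_b = float(np.exp(full.x[i + int(use_donor)])) if use_batch else 0.0
    return CompositionResult(
        cluster=str(cluster_label),
        comparison=f"{ga}_vs_{gb}",
        odds_ratio=or_,
        ci_low=lo,
        ci_high=hi,
        p=min(1.0, max(p, np.finfo(float).tiny)),
        n_units=len(units),
        separated=bool(separated),
        sigma_donor=sd_d,
        sigma_batch=sd_b,
    )


def _wald_se(params, idx, X, *args) -> float:
    """Numerical observed-information SE of one fixed effect.

    The full Hessian can be singular when a random-effect scale sits at
    its boundary; in that case the fixed-effect block with the scales
    held at their estimates is used instead.
    """
    h = 1e-4
    n_fixed = X.shape[1]

    def f(x):
        return _masc_nll(x, X, *args)

    def hess(indices):
        k = len(indices)
        H = np.zeros((k, k))
        f0 = f(params)
        for a in range(k):
            for b in range(a, k):
                pa = params.copy()
                pa[indices[a]] += h
                pb = params.copy()
                pb[indices[b]] += h
                pab = pa.copy()
                pab[indices[b]] += h
                H[a, b] = H[b, a] = (f(pab) - f(pa) - f(pb) + f0) / h**2
        return H

    for indices in (list(range(len(params))), list(range(n_fixed))):
        H = hess(indices)
        try:
            cov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            continue
        v = cov[indices.index(idx), indices.index(idx)]
        if v > 0:
            return float(np.sqrt(v))
    return np.nan


def pseudobulk_de(
    nuclei: AnnData,
    cell_class: str,
    min_nuclei: int = 30,
    min_donor_fraction: float = 0.75,
    age_span: float = AGE_GROUP_MIDPOINTS["old"] - AGE_GROUP_MIDPOINTS["young"],
) -> pd.DataFrame:
    """Pseudobulk linear-model DE against age for one broad class.

    Genes must be expressed in >= ``min_nuclei`` nuclei of the class and
    detected (nonzero pseudobulk) in >= ``min_donor_fraction`` of the
    young donors or of the old donors (middle donors are not used for
    the detection rule). Per-donor log2 CPM is regressed on age in years
    plus sex and batch; the effect is reported as log2FC over the
    young-to-old age span (default 35 years). BH-adjusted q-values.
    """
    sub = nuclei[nuclei.obs["broad_class"] == cell_class]
    if sub.n_obs == 0:
        raise ValueError(f"no nuclei of class {cell_class!r}")
    X = counts_matrix(sub)
    obs = sub.obs

    donors = obs["donor_id"].unique().tolist()
    if len(donors) < 3:
        raise ValueError("need at least 3 donors for pseudobulk DE")
    pb = np.vstack(
        [X[(obs["donor_id"] == d).to_numpy()].sum(axis=0) for d in donors]
    )
    meta = (
        obs.groupby("donor_id", observed=True)
        .agg(
            age=("age", "first"),
            age_group=("age_group", "first"),
            sex=("sex", "first"),
            batch=("batch", "first"),
        )
        .loc[donors]
        .reset_index()
    )

    expressed = (X > 0).sum(axis=0) >= min_nuclei
    detected = pb > 0
    keep_det = np.zeros(X.shape[1], dtype=bool)
    for grp in ("young", "old"):
        rows = (meta["age_group"] == grp).to_numpy()
        if rows.any():
            keep_det |= detected[rows].mean(axis=0) >= min_donor_fraction
    keep = expressed & keep_det
    if not keep.any():
        raise ValueError("no genes pass the detection filters")
    genes = sub.var_names[keep]
    pb = pb[:, keep]

    logcpm = np.log2(pb / pb.sum(axis=1, keepdims=True) * 1e6 + 1.0)
    design_cols = {"intercept": np.ones(len(meta)), "age": meta["age"].to_numpy(float)}
    if meta["sex"].nunique() > 1:
        design_cols["sex_F"] = (meta["sex"] == "F").to_numpy(float)
    batches = sorted(meta["batch"].unique())
    for b in batches[1:]:
        design_cols[f"batch_{b}"] = (meta["batch"] == b).to_numpy(float)
    names = list(design_cols)
    D = np.column_stack(list(design_cols.values()))
    rank = np.linalg.matrix_rank(D)
    if rank < D.shape[1]:
        bad = _confounded_columns(D, names)
        raise ValueError(f"rank-deficient design; confounded columns: {bad}")
    if len(meta) <= D.shape[1]:
        raise ValueError("fewer donors than design columns")

    coef, _, _, _ = np.linalg.lstsq(D, logcpm, rcond=None)
    resid = logcpm - D @ coef
    dof = len(meta) - D.shape[1]
    s2 = (resid**2).sum(axis=0) / dof
    xtx_inv = np.linalg.inv(D.T @ D)
    j = names.index("age")
    se = np.sqrt(s2 * xtx_inv[j, j])
    tvals = np.divide(coef[j], se, out=np.zeros_like(se), where=se > 0)
    p = 2 * stats.t.sf(np.abs(tvals), dof)
    q = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "gene": genes,
            "log2fc": coef[j] * age_span,
            "t": tvals,
            "p": p,
            "q": q,
        }
    ).sort_values("p", ignore_index=True)


def _confounded_columns(D: np.ndarray, names: list[str]) -> list[str]:
    from scipy.linalg import qr

    _, r, piv = qr(D, pivoting=True, mode="economic")
    rank = int(np.sum(np.abs(np.diag(r)) > 1e-8 * abs(r[0, 0])))
    return [names[i] for i in sorted(piv[rank:])]


def auc_rank_markers(
    nuclei: AnnData, group_a_mask, group_b_mask
) -> pd.DataFrame:
    """Per-gene ROC AUC of expression as a classifier of group A vs B.

    AUC is computed from ranks (Mann-Whitney U with ties mid-ranked);
    genes are sorted by |AUC - 0.5| descending.
    """
    a = np.asarray(group_a_mask, dtype=bool)
    b = np.asarray(group_b_mask, dtype=bool)
    if not a.any() or not b.any():
        raise ValueError("both groups must be non-empty")
    X = counts_matrix(nuclei)
    Xa, Xb = X[a], X[b]
    na, nb = Xa.shape[0], Xb.shape[0]
    both = np.vstack([Xa, Xb])
    ranks = stats.rankdata(both, axis=0)
    U = ranks[:na].sum(axis=0) - na * (na + 1) / 2.0
    auc = U / (na * nb)
    out = pd.DataFrame(
        {"gene": nuclei.var_names, "auc": auc, "effect": np.abs(auc - 0.5)}
    )
    return out.sort_values("effect", ascending=False, ignore_index=True)
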