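"""Hierarchical Bayesian zero-inflated-Poisson spatial expression model.

For one gene, counts at spot ``s`` follow

    y_s ~ ZIP(lambda_s, theta),
    log lambda_s = beta[aar(s), group(s)] + psi_s + eps_s,

with a hierarchical prior on the characteristic rates,
``beta[a, g] ~ N(mu_a, sigma_beta^2)`` and ``mu_a ~ N(0, 2^2)``; an
intrinsic conditional-autoregressive (ICAR) prior on ``psi`` over the
spot adjacency graph, restricted within arrays, with a fixed scale
``tau`` and a soft sum-to-zero constraint per array; i.i.d. spot noise
``eps ~ N(0, sigma^2)`` with a tight half-Normal hyperprior on
``sigma``; and a Beta(1,2) prior on the per-gene dropout probability
``theta``. ``beta`` is on the natural-log counts/spot scale. ``tau`` is
a model scale rather than a free parameter because a jointly maximized
field scale is unidentified against dropout (see
:mod:`senespat._zip_objective`).

Inference is maximum a posteriori with a Laplace (Gaussian)
approximation of the marginal posterior of ``(beta, mu)``. The spot
noise ``eps`` is integrated out of the likelihood by Gauss-Hermite
quadrature (see :mod:`senespat._zip_objective` for why it is not
optimized as a free vector); the smooth spatial field ``psi`` is
optimized jointly and its uncertainty propagates into the beta
covariance through a Schur complement of the observed information. An
affine-invariant ensemble MCMC backend (emcee) is available for fits
without the latent spatial field and serves as an audit route for the
Laplace approximation.

Differential expression between donor groups is scored with the
Savage-Dickey density ratio: BF = prior density of the group difference
at zero over its posterior density at zero, with a Bayes-factor
threshold of 3 (tiers at 3/10/30) and a |log2 fold change| > 1 gate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import optimize, sparse
from scipy.sparse.linalg import splu
from scipy.stats import gaussian_kde, norm

from ._grid import edges_from_coords
from ._zip_objective import ZipObjective, _sigmoid
from .datasets import AARS, AGE_GROUPS, counts_matrix
from .priors import MU_PRIOR_SD, SIGMA_BETA

BF_CLIP = (1e-6, 1e6)


@dataclass
class SpotGraph:
    """Rook adjacency among surviving spots, restricted within arrays."""

    n_spots: int
    edges: np.ndarray  # (m, 2), i < j
    array_of_spot: np.ndarray

    def degrees(self) -> np.ndarray:
        d = np.zeros(self.n_spots, dtype=int)
        if len(self.edges):
            np.add.at(d, self.edges[:, 0], 1)
            np.add.at(d, self.edges[:, 1], 1)
        return d


@dataclass
class FitConfig:
    """Options for a single-gene fit."""

    include_spatial: bool = True
    include_noise: bool = True
    #: fixed scale of the ICAR spatial field (psi = tau_psi * u)
    tau_psi: float = 0.3
    n_draws: int = 1000
    backend: str = "laplace"  # or "mcmc"
    seed: int = 0
    mcmc_steps: int = 2000
    mcmc_burn: int = 800
    grad_tol: float = 5e-3


@dataclass
class PosteriorSummary:
    """Posterior draws and point summaries for one gene."""

    gene: str
    aars: list[str]
    groups: list[str]
    beta_mean: np.ndarray  # (A, G)
    beta_draws: np.ndarray  # (n_draws, A, G)
    theta: float
    psi: np.ndarray
    epsilon: np.ndarray
    lambda_mean: np.ndarray
    diagnostics: dict = field(default_factory=dict)

    def delta_draws(self, aar: str, group_a: str, group_b: str) -> np.ndarray:
        """Draws of beta[aar, group_a] - beta[aar, group_b]."""
        a = self.aars.index(aar)
        ga, gb = self.groups.index(group_a), self.groups.index(group_b)
        return self.beta_draws[:, a, ga] - self.beta_draws[:, a, gb]

    def overall_delta_draws(self, group_a: str, group_b: str) -> np.ndarray:
        """AAR-averaged group-difference draws."""
        ga, gb = self.groups.index(group_a), self.groups.index(group_b)
        return (self.beta_draws[:, :, ga] - self.beta_draws[:, :, gb]).mean(axis=1)


def build_spot_graph(ds: AnnData) -> SpotGraph:
    """Rook-adjacency graph of the dataset's spots, within-array only."""
    arrays = ds.obs["array_id"].to_numpy()
    row = ds.obs["row"].to_numpy(dtype=int)
    col = ds.obs["col"].to_numpy(dtype=int)
    all_edges = []
    for arr in pd.unique(arrays):
        idx = np.flatnonzero(arrays == arr)
        e = edges_from_coords(row[idx], col[idx])
        if len(e):
            all_edges.append(idx[e])
    edges = np.vstack(all_edges) if all_edges else np.empty((0, 2), dtype=int)
    edges = np.sort(edges, axis=1)
    return SpotGraph(n_spots=ds.n_obs, edges=edges, array_of_spot=arrays)


def _beta_covariance(obj: ZipObjective, z: np.ndarray) -> np.ndarray:
    """Laplace covariance of (beta, mu), marginal over the spatial field.

    Hyperparameters (tau, sigma, theta) are held at their MAP values;
    the latent spatial field's uncertainty enters via the Schur
    complement of the observed information.
    """
    d = obj.spot_curvature(z)
    nc, na = obj.n_cells, obj.n_aars
    K = nc + na
    H_bb = np.zeros((K, K))
    dsum = np.bincount(obj.cell_idx, weights=d, minlength=nc)
    H_bb[:nc, :nc] = np.diag(dsum + 1.0 / SIGMA_BETA**2)
    for c in range(nc):
        a = obj.aar_of_cell[c]
        H_bb[c, nc + a] -= 1.0 / SIGMA_BETA**2
        H_bb[nc + a, c] -= 1.0 / SIGMA_BETA**2
    for a in range(na):
        H_bb[nc + a, nc + a] = (
            np.sum(obj.aar_of_cell == a) / SIGMA_BETA**2 + 1.0 / MU_PRIOR_SD**2
        )
    if not obj.cfg.include_spatial:
        return np.linalg.inv(H_bb)

    n = obj.n
    tau = obj.cfg.tau_psi
    i, j = obj.edges[:, 0], obj.edges[:, 1]
    ones = np.ones(len(i))
    L = sparse.coo_matrix(
        (
            np.concatenate([ones, ones, -ones, -ones]),
            (np.concatenate([i, j, i, j]), np.concatenate([i, j, j, i])),
        ),
        shape=(n, n),
    ).tocsr()
    rows_soft = []
    for mask in obj.array_masks:
        scale = 0.001 * len(mask) * tau
        v = np.zeros(n)
        v[mask] = 1.0 / scale
        rows_soft.append(v)
    S = np.array(rows_soft)
    H_ll = (sparse.diags(d) + L / tau**2 + sparse.csr_matrix(S.T @ S)).tocsc()

    H_bl = np.zeros((K, n))
    for c in range(nc):
        mask = obj.cell_idx == c
        H_bl[c, mask] = d[mask]
    lu = splu(H_ll)
    X = lu.solve(H_bl.T)  # (n, K)
    return np.linalg.inv(H_bb - H_bl @ X)


def fit_gene_model(
    ds: AnnData, graph: SpotGraph, gene: str, cfg: FitConfig | None = None
) -> PosteriorSummary:
    """Fit the hierarchical ZIP model for one gene.

    Returns posterior draws of ``beta`` (Laplace approximation by
    default, ensemble MCMC when ``cfg.backend == "mcmc"`` and the
    spatial field is disabled), point estimates of the spot fields and
    dropout probability, and convergence diagnostics. Non-convergence is
    flagged in ``diagnostics``, never silent.
    """
    cfg = cfg or FitConfig()
    if gene not in ds.var_names:
        raise KeyError(f"gene {gene!r} not in dataset")
    y = counts_matrix(ds[:, gene]).ravel()
    aar = ds.obs["aar"].astype(str).to_numpy()
    group = ds.obs["age_group"].astype(str).to_numpy()
    aars = [a for a in AARS if a in set(aar)]
    groups = [g for g in AGE_GROUPS if g in set(group)]
    na, ng = len(aars), len(groups)
    aar_idx = np.array([aars.index(a) for a in aar])
    grp_idx = np.array([groups.index(g) for g in group])
    cell_idx = aar_idx * ng + grp_idx
    aar_of_cell = np.arange(na * ng) // ng

    obj = ZipObjective(y, cell_idx, na * ng, aar_of_cell, na, graph, cfg)
    if cfg.backend == "mcmc":
        if cfg.include_spatial:
            raise ValueError(
                "the mcmc backend supports fits without the latent spatial "
                "field; use the laplace backend for the full spatial model"
            )
        return _fit_mcmc(obj, gene, aars, groups, cfg)

    z0 = obj.initial()
    res = optimize.minimize(
        obj, z0, jac=True, method="L-BFGS-B", bounds=obj.bounds(),
        options={"maxiter": 500},
    )
    z = res.x
    grad_norm = float(np.max(np.abs(res.jac)) / max(1.0, len(y) ** 0.5))
    converged = bool(res.success or grad_norm < cfg.grad_tol)

    cov = _beta_covariance(obj, z)
    nb = na * ng
    mean_b = z[obj.sl_beta]
    cov_b = cov[:nb, :nb]
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 11]))
    chol = np.linalg.cholesky(cov_b + 1e-10 * np.eye(nb))
    draws = mean_b + rng.standard_normal((cfg.n_draws, nb)) @ chol.T

    theta = float(_sigmoid(z[obj.idx_logit_theta]))
    psi = cfg.tau_psi * z[obj.sl_u] if cfg.include_spatial else np.zeros(len(y))
    eps = obj.noise_posterior_mean(z)
    lam = np.exp(obj.spot_mean(z) + eps)
    return PosteriorSummary(
        gene=gene,
        aars=aars,
        groups=groups,
        beta_mean=mean_b.reshape(na, ng),
        beta_draws=draws.reshape(cfg.n_draws, na, ng),
        theta=theta,
        psi=psi,
        epsilon=eps,
        lambda_mean=lam,
        diagnostics={
            "backend": "laplace",
            "converged": converged,
            "grad_norm": grad_norm,
            "beta_sd": np.sqrt(np.diag(cov_b)).reshape(na, ng),
        },
    )


def _fit_mcmc(obj, gene, aars, groups, cfg: FitConfig) -> PosteriorSummary:
    import emcee

    na, ng = len(aars), len(groups)
    nb = na * ng
    ndim = obj.n_params

    def log_prob(z):
        nll, _ = obj(z)
        return -nll if np.isfinite(nll) else -np.inf

    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 12]))
    z0 = obj.initial()
    nwalkers = max(2 * ndim + 2, 8)
    p0 = z0 + 0.05 * rng.standard_normal((nwalkers, ndim))
    sampler = emcee.EnsembleSampler(nwalkers, ndim, log_prob)
    sampler.run_mcmc(p0, cfg.mcmc_steps, progress=False,
                     skip_initial_state_check=True)
    chain = sampler.get_chain(discard=cfg.mcmc_burn, flat=True)
    take = rng.choice(len(chain), size=cfg.n_draws, replace=len(chain) < cfg.n_draws)
    draws = chain[take][:, :nb]
    acc = float(np.mean(sampler.acceptance_fraction))
    theta = float(np.mean(_sigmoid(chain[:, obj.idx_logit_theta])))
    mean_b = chain[:, :nb].mean(axis=0)
    return PosteriorSummary(
        gene=gene,
        aars=aars,
        groups=groups,
        beta_mean=mean_b.reshape(na, ng),
        beta_draws=draws.reshape(cfg.n_draws, na, ng),
        theta=theta,
        psi=np.zeros(obj.n),
        epsilon=np.zeros(obj.n),
        lambda_mean=np.exp(mean_b[obj.cell_idx]),
        diagnostics={
            "backend": "mcmc",
            "converged": 0.1 < acc < 0.9,
            "acceptance_fraction": acc,
        },
    )


def fit_genes(
    ds: AnnData, graph: SpotGraph, genes, cfg: FitConfig | None = None
) -> dict[str, PosteriorSummary]:
    """Fit each gene independently (no shared mutable state)."""
    return {g: fit_gene_model(ds, graph, g, cfg) for g in genes}


def lambda_matrix(posteriors: dict[str, PosteriorSummary], obs_names) -> pd.DataFrame:
    """Spot x gene posterior mean expression table for coexpression."""
    return pd.DataFrame(
        {g: p.lambda_mean for g, p in posteriors.items()},
        index=list(obs_names),
    )


def savage_dickey_bf(delta_draws: np.ndarray, prior_sd: float) -> float:
    """Savage-Dickey Bayes factor for a nonzero group difference.

    BF = prior density at 0 / posterior density at 0, the posterior
    density estimated from the draws by a Gaussian KDE with Silverman
    bandwidth. Clipped to [1e-6, 1e6]. Requires >= 500 draws.
    """
    delta_draws = np.asarray(delta_draws, dtype=float)
    if delta_draws.size < 500:
        raise ValueError(f"need >= 500 posterior draws, got {delta_draws.size}")
    prior_at_zero = norm.pdf(0.0, loc=0.0, scale=prior_sd)
    if np.std(delta_draws) == 0:
        post_at_zero = np.inf if delta_draws[0] == 0 else 0.0
    else:
        post_at_zero = float(gaussian_kde(delta_draws, bw_method="silverman")(0.0)[0])
    if post_at_zero <= 0:
        return BF_CLIP[1]
    return float(np.clip(prior_at_zero / post_at_zero, *BF_CLIP))


def delta_prior_sd(n_aars_averaged: int = 1) -> float:
    """Prior sd of a (possibly AAR-averaged) group difference in beta."""
    return SIGMA_BETA * np.sqrt(2.0 / n_aars_averaged)


def significance_tier(bf: float) -> int:
    """Evidence tier: 1 for BF>3, 2 for BF>10, 3 for BF>30, else 0."""
    return int(bf > 3) + int(bf > 10) + int(bf > 30)


def run_de(
    posteriors,
    comparison: tuple[str, str] = ("old", "young"),
    bf_threshold: float = 3.0,
    lfc_threshold: float = 1.0,
) -> pd.DataFrame:
    """Savage-Dickey differential expression per gene x AAR.

    ``comparison = (a, b)`` scores beta[a] - beta[b]. A gene/AAR is
    significant when BF > ``bf_threshold`` and |log2FC| >
    ``lfc_threshold``; log2FC = mean(delta) / ln 2.
    """
    if isinstance(posteriors, dict):
        posteriors = list(posteriors.values())
    ga, gb = comparison
    rows = []
    for post in posteriors:
        if ga not in post.groups or gb not in post.groups:
            raise ValueError(
                f"comparison {comparison} not available for gene {post.gene}; "
                f"groups present: {post.groups}"
            )
        for aar in post.aars:
            d = post.delta_draws(aar, ga, gb)
            bf = savage_dickey_bf(d, prior_sd=delta_prior_sd())
            lfc = float(np.mean(d) / np.log(2.0))
            rows.append(
                {
                    "gene": post.gene,
                    "aar": aar,
                    "comparison": f"{ga}_vs_{gb}",
                    "bf": bf,
                    "log2fc": lfc,
                    "tier": significance_tier(bf),
                    "significant": bool(bf > bf_threshold and abs(lfc) > lfc_threshold),
                }
            )
    return pd.DataFrame(rows)
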