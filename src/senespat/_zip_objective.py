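"""Negative log posterior of the hierarchical ZIP spatial model.

The spot-specific noise eps ~ N(0, sigma^2) is integrated out of the
likelihood by Gauss-Hermite quadrature (a zero-inflated
Poisson-lognormal mixture) rather than optimized as a free per-spot
vector: with one observation per spot, joint maximization over such
incidental parameters is inconsistent and biases beta downward. The
spatial field psi = tau * u is kept latent (unit ICAR prior on u) with
tau a FIXED model scale, not a free parameter: at a joint mode a free
tau escapes any scalar prior and lets the field carve out individual
ZIP zeros (gaining ~0.5 nat per zero spot), which drives theta to 0 and
beta down by about half the squared field amplitude. With tau fixed,
spot-wise wiggles cost quadratically in u while genuinely smooth
laminar patterns remain cheap.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import pandas as pd

from .priors import MU_PRIOR_SD, SIGMA_BETA, SIGMA_EPS_PRIOR_SCALE

_GH_NODES = 15


@lru_cache(maxsize=1)
def _gh():
    t, w = np.polynomial.hermite.hermgauss(_GH_NODES)
    return np.sqrt(2.0) * t, np.log(w / np.sqrt(np.pi))


def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


class ZipObjective:
    """Value/gradient of the negative log posterior for one gene.

    Parameter vector layout: beta (cells = AAR x group), mu (AARs),
    [u (spots) if spatial], [log tau if spatial], [log sigma if noise],
    logit theta.
    """

    def __init__(self, y, cell_idx, n_cells, aar_of_cell, n_aars, graph, cfg):
        self.y = np.asarray(y, dtype=float)
        self.pos = self.y > 0
        self.cell_idx = cell_idx
        self.n_cells = n_cells
        self.aar_of_cell = aar_of_cell
        self.n_aars = n_aars
        self.cfg = cfg
        self.n = len(y)
        self.graph = graph
        if cfg.include_spatial:
            self.edges = graph.edges
            arr_ids = pd.unique(np.asarray(graph.array_of_spot))
            self.array_masks = [
                np.flatnonzero(graph.array_of_spot == a) for a in arr_ids
            ]
        k = n_cells + n_aars
        self.sl_beta = slice(0, n_cells)
        self.sl_mu = slice(n_cells, k)
        if cfg.include_spatial:
            self.sl_u = slice(k, k + self.n)
            k += self.n
        self.idx_lsig = k if cfg.include_noise else None
        k += int(cfg.include_noise)
        self.idx_logit_theta = k
        self.n_params = k + 1
        if cfg.include_noise:
            self.nodes, self.log_w = _gh()
        else:
            self.nodes, self.log_w = np.zeros(1), np.zeros(1)

    def initial(self) -> np.ndarray:
        z = np.zeros(self.n_params)
        sums = np.bincount(self.cell_idx, weights=self.y, minlength=self.n_cells)
        counts = np.bincount(self.cell_idx, minlength=self.n_cells).astype(float)
        beta0 = np.log((sums + 0.1) / np.maximum(counts, 1.0))
        z[self.sl_beta] = beta0
        for a in range(self.n_aars):
            z[self.sl_mu][a] = beta0[self.aar_of_cell == a].mean()
        if self.idx_lsig is not None:
            z[self.idx_lsig] = np.log(0.1)
        z[self.idx_logit_theta] = -2.0
        return z

    def bounds(self):
        b = [(-30.0, 30.0)] * (self.n_cells + self.n_aars)
        if self.cfg.include_spatial:
            b += [(-12.0, 12.0)] * self.n
        if self.cfg.include_noise:
            b += [(-6.0, 3.0)]
        b += [(-12.0, 12.0)]
        return b

    def spot_mean(self, z) -> np.ndarray:
        """m_s: log-rate before the marginalized noise component."""
        m = z[self.sl_beta][self.cell_idx].copy()
        if self.cfg.include_spatial:
            m += self.cfg.tau_psi * z[self.sl_u]
        return m

    def _mixture(self, z):
        """Per-spot, per-node log components and responsibilities."""
        theta = _sigmoid(z[self.idx_logit_theta])
        sigma = np.exp(z[self.idx_lsig]) if self.cfg.include_noise else 0.0
        m = self.spot_mean(z)
        eta = np.clip(m[:, None] + sigma * self.nodes[None, :], -40.0, 40.0)
        lam = np.exp(eta)
        pos = self.pos
        log_p = np.empty_like(lam)
        log_p[pos] = np.log1p(-theta) + self.y[pos, None] * eta[pos] - lam[pos]
        log_p0 = np.logaddexp(np.log(theta), np.log1p(-theta) - lam[~pos])
        log_p[~pos] = log_p0
        mix = log_p + self.log_w[None, :]
        L = np.logaddexp.reduce(mix, axis=1)
        r = np.exp(mix - L[:, None])
        return theta, sigma, lam, L, r, log_p

    def __call__(self, z):
        cfg = self.cfg
        theta, sigma, lam, L, r, log_p = self._mixture(z)
        pos = self.pos
        y = self.y

        # d log p / d m and d log p / d theta per component
        a = np.where(pos[:, None], y[:, None] - lam, 0.0)
        zer = ~pos
        wtil = np.exp(np.log1p(-theta) - lam[zer] - log_p[zer])
        a[zer] = -wtil * lam[zer]
        g_m = -(r * a).sum(axis=1)

        nll = -L.sum()
        grad = np.zeros_like(z)
        beta, mu = z[self.sl_beta], z[self.sl_mu]

        gb = np.bincount(self.cell_idx, weights=g_m, minlength=self.n_cells)
        dev = (beta - mu[self.aar_of_cell]) / SIGMA_BETA**2
        nll += 0.5 * np.sum((beta - mu[self.aar_of_cell]) ** 2) / SIGMA_BETA**2
        nll += 0.5 * np.sum(mu**2) / MU_PRIOR_SD**2
        grad[self.sl_beta] = gb + dev
        grad[self.sl_mu] = (
            -np.bincount(self.aar_of_cell, weights=dev, minlength=self.n_aars)
            + mu / MU_PRIOR_SD**2
        )

        if cfg.include_spatial:
            u = z[self.sl_u]
            gu = cfg.tau_psi * g_m
            i, j = self.edges[:, 0], self.edges[:, 1]
            diff = u[i] - u[j]
            nll += 0.5 * np.sum(diff**2)
            np.add.at(gu, i, diff)
            np.add.at(gu, j, -diff)
            for mask in self.array_masks:
                scale = 0.001 * len(mask)
                s = u[mask].sum()
                nll += 0.5 * (s / scale) ** 2
                gu[mask] += s / scale**2
            grad[self.sl_u] = gu

        if cfg.include_noise:
            lsig = z[self.idx_lsig]
            g_sig = -(r * a * self.nodes[None, :]).sum(axis=1)
            s2 = (sigma / SIGMA_EPS_PRIOR_SCALE) ** 2
            nll += 0.5 * s2 - lsig
            grad[self.idx_lsig] = np.sum(g_sig) * sigma + s2 - 1.0

        # theta: d log p / d theta per component
        c = np.empty_like(lam)
        c[pos] = -1.0 / (1.0 - theta)
        c[zer] = (1.0 - np.exp(-lam[zer])) * np.exp(
            np.minimum(-log_p[zer], 500.0)
        )
        g_t = -(r * c).sum(axis=1).sum()
        nll -= 2.0 * np.log1p(-theta) + np.log(theta)  # Beta(1,2) + Jacobian
        g_t += 2.0 / (1.0 - theta) - 1.0 / theta
        grad[self.idx_logit_theta] = g_t * theta * (1.0 - theta)
        return nll, grad

    def spot_curvature(self, z) -> np.ndarray:
        """d^2 NLL / d m_s^2 of the marginal likelihood (PSD-clipped)."""
        theta, sigma, lam, L, r, log_p = self._mixture(z)
        pos = self.pos
        a = np.where(pos[:, None], self.y[:, None] - lam, 0.0)
        zer = ~pos
        wtil = np.exp(np.log1p(-theta) - lam[zer] - log_p[zer])
        a[zer] = -wtil * lam[zer]
        h = np.where(pos[:, None], -lam, 0.0)
        p0 = np.exp(log_p[zer])
        h[zer] = -(lam[zer] * wtil) * (1.0 - lam[zer] * theta / p0)
        mean_a = (r * a).sum(axis=1)
        second = (r * (h + a**2)).sum(axis=1) - mean_a**2
        return np.maximum(-second, 1e-10)

    def noise_posterior_mean(self, z) -> np.ndarray:
        """Posterior mean of the marginalized spot noise eps per spot."""
        if not self.cfg.include_noise:
            return np.zeros(self.n)
        _, sigma, _, _, r, _ = self._mixture(z)
        return sigma * (r * self.nodes[None, :]).sum(axis=1)
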