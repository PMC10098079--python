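"""Independent brute-force oracles and toy instances used only by tests."""

import math

import numpy as np
from numpy.polynomial.hermite_e import hermegauss


def tiny_mixed_instance(seed=42, sigma2=0.25):
    """2 blocks x 2 plots x 3 culms simulated from known NLME parameters.

    Returns (dataset, beta, psi_block, var_plot, sigma2, gamma) — small
    enough for exact quadrature over all three random effects.
    """
    from bamboohcb import CulmRecord, Dataset, PlotRecord, derive_covariates

    rng = np.random.default_rng(seed)
    beta = np.array([0.84, -0.079, -0.002, -0.344])
    psi_b = np.array([[0.012, -0.0004], [-0.0004, 6e-5]])
    var_plot = 2.1e-4
    gamma = -0.018
    blocks, plots, culms = ["A", "B"], [], []
    for b in blocks:
        for j in range(2):
            pid = f"{b}{j}"
            plots.append(PlotRecord(plot_id=pid, block_id=b,
                                    cd=float(rng.uniform(0.4, 0.87))))
            for k in range(3):
                dbh = float(rng.uniform(7, 13))
                h = float(2.6 * dbh ** 0.65 + rng.normal(0, 1))
                culms.append(CulmRecord(b, pid, f"c{k}", dbh=dbh, h=h))
    ds = derive_covariates(Dataset(blocks, plots, culms))
    Lb = np.linalg.cholesky(psi_b)
    u_b = {b: Lb @ rng.standard_normal(2) for b in blocks}
    u_p = {p.plot_id: math.sqrt(var_plot) * rng.standard_normal() for p in plots}
    cd_of = {p.plot_id: p.cd for p in plots}
    for c in ds.culms:
        x = (beta[0] + u_b[c.block_id][0]) \
            + (beta[1] + u_b[c.block_id][1] + u_p[c.plot_id]) * c.dbh \
            + beta[2] * c.bal + beta[3] * cd_of[c.plot_id]
        mu = c.h / (1 + math.exp(x))
        noise = math.sqrt(sigma2) * math.exp(gamma * c.h) * rng.standard_normal()
        c.hcb = float(np.clip(mu + noise, 0.02 * c.h, 0.98 * c.h))
    return ds, beta, psi_b, var_plot, sigma2, gamma


def quadrature_loglik(ds, beta, psi_block, var_plot, sigma2, gamma, n_nodes=41):
    """Exact marginal log-likelihood of the two-level logistic model by
    nested Gauss-Hermite quadrature.

    Integrates the bivariate block effect (intercept, DBH slope) on an
    n_nodes^2 grid and the scalar plot-level DBH-slope effect on n_nodes
    points per plot; residuals are N(0, sigma2 * exp(2*gamma*h)).
    Feasible only for a handful of culms; serves as the reference for the
    engine's linearization-based likelihood.
    """
    nodes, wts = hermegauss(n_nodes)           # weight exp(-z^2/2)
    wts = wts / math.sqrt(2.0 * math.pi)       # normal quadrature weights
    Lb = np.linalg.cholesky(np.asarray(psi_block, dtype=float))
    sp = math.sqrt(var_plot)
    cd_of = {p.plot_id: p.cd for p in ds.plots}

    # grid of block effects: (G, 2) with G = n_nodes^2
    Z1, Z2 = np.meshgrid(nodes, nodes, indexing="ij")
    U = np.stack([Z1.ravel(), Z2.ravel()], axis=1) @ Lb.T      # (G, 2)
    Wg = np.outer(wts, wts).ravel()                            # (G,)

    total = 0.0
    for block in ds.blocks:
        plots = [p for p in ds.plots if p.block_id == block]
        log_prod = np.zeros(U.shape[0])
        for p in plots:
            culms = [c for c in ds.culms if c.plot_id == p.plot_id]
            dbh = np.array([c.dbh for c in culms])
            h = np.array([c.h for c in culms])
            bal = np.array([c.bal for c in culms])
            y = np.array([c.hcb for c in culms])
            sd = np.sqrt(sigma2) * np.exp(gamma * h)
            v = sp * nodes                                     # (Q,)
            # x: (G, Q, m)
            x = (beta[0] + U[:, 0])[:, None, None] \
                + (beta[1] + U[:, 1])[:, None, None] * dbh[None, None, :] \
                + v[None, :, None] * dbh[None, None, :] \
                + beta[2] * bal[None, None, :] + beta[3] * cd_of[p.plot_id]
            mu = h[None, None, :] / (1.0 + np.exp(x))
            logphi = -0.5 * ((y - mu) / sd) ** 2 - np.log(sd * math.sqrt(2 * math.pi))
            loglik = logphi.sum(axis=2)                        # (G, Q)
            mx = loglik.max(axis=1, keepdims=True)
            inner = np.sum(np.exp(loglik - mx) * wts[None, :], axis=1)
            # log-sum-exp keeps degenerate corners from underflowing
            log_prod += mx[:, 0] + np.log(np.maximum(inner, 1e-300))
        m = log_prod.max()
        total += m + math.log(float(np.sum(Wg * np.exp(log_prod - m))))
    return total
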