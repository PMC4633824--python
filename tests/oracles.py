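"""Independent reference computations used to validate the samplers.

Everything here is deliberately brute force: direct enumeration, dense
quadrature, or plain Metropolis chains, kept separate from the
implementation paths they check.
"""

from __future__ import annotations

from itertools import combinations, product

import numpy as np
from scipy.special import comb, expit, logsumexp

from eqtel.expression_model import log_marginal


def hwe_brute_force(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact HWE P by direct conditional probabilities (Levene/Haldane).

    P(n_het | n, n_minor) = C(n, n_hom_r) C(n - n_hom_r, n_het) 2^n_het
                            / C(2n, n_minor) ... computed directly from
    factorial ratios with exact floats at small n.
    """
    n = n_aa + n_ab + n_bb
    n_minor = 2 * min(n_aa, n_bb) + n_ab
    probs = {}
    for het in range(n_minor % 2, n_minor + 1, 2):
        hom_r = (n_minor - het) // 2
        hom_c = n - het - hom_r
        if hom_c < 0:
            continue
        val = (
            comb(n, hom_r, exact=True)
            * comb(n - hom_r, het, exact=True)
            * 2**het
            / comb(2 * n, n_minor, exact=True)
        )
        # remaining multinomial factor: choose hom_c slots is forced
        probs[het] = val
    total = sum(probs.values())
    probs = {k: v / total for k, v in probs.items()}
    p_obs = probs[n_ab]
    return sum(v for v in probs.values() if v <= p_obs * (1 + 1e-12))


def mh_logistic(F, labels, b, prior_var, n_iter=40000, step=0.25, seed=0,
                burn=5000):
    """Random-walk Metropolis reference for the Bayesian logistic posterior."""
    rng = np.random.default_rng(seed)
    F = np.asarray(F, float)
    labels = np.asarray(labels, float)
    b = np.asarray(b, float)
    d = F.shape[1]
    pv = np.broadcast_to(np.asarray(prior_var, float), (d,))

    def logpost(a):
        psi = F @ a
        ll = labels @ psi - np.logaddexp(0.0, psi).sum()
        lp = -0.5 * np.sum((a - b) ** 2 / pv)
        return ll + lp

    a = b.copy()
    lp = logpost(a)
    draws = np.empty((n_iter, d))
    for t in range(n_iter):
        prop = a + step * rng.standard_normal(d)
        lpp = logpost(prop)
        if np.log(rng.uniform()) < lpp - lp:
            a, lp = prop, lpp
        draws[t] = a
    return draws[burn:]


def enumerate_gamma_posterior(y, X, prior_incl, g, max_size=None):
    """Exact PIPs by summing all gamma configurations (fixed priors)."""
    y = np.asarray(y, float)
    y = y - y.mean()
    X = np.asarray(X, float)
    p = X.shape[1]
    prior_incl = np.asarray(prior_incl, float)
    max_size = max_size if max_size is not None else len(y) - 3
    lw, cfgs = [], []
    for k in range(min(p, max_size) + 1):
        for sub in combinations(range(p), k):
            lm = log_marginal(y, X[:, list(sub)] if k else np.empty((len(y), 0)), g)
            lp = (
                np.log(prior_incl[list(sub)]).sum()
                + np.log1p(-prior_incl).sum()
                - np.log1p(-prior_incl[list(sub)]).sum()
            )
            lw.append(lm + lp)
            cfgs.append(sub)
    lw = np.array(lw)
    w = np.exp(lw - logsumexp(lw))
    pip = np.zeros(p)
    for cfg, wt in zip(cfgs, w):
        for i in cfg:
            pip[i] += wt
    return pip


def joint_enumeration(y, X, F, pi, rho, b, prior_var, g,
                      grid_half_width=6.0, grid_n=41):
    """Exact joint posterior of the coupled model on a tiny instance.

    Enumerates gamma and theta over {0,1}^p for one gene and integrates the
    shared logistic weights alpha over a dense 2-D grid (F must have two
    columns: bias + one feature). Returns (pip, E[theta], and the alpha
    posterior mean) marginals.
    """
    y = np.asarray(y, float)
    y = y - y.mean()
    X = np.asarray(X, float)
    F = np.asarray(F, float)
    p = X.shape[1]
    assert F.shape == (p, 2)
    pv = np.broadcast_to(np.asarray(prior_var, float), (2,))
    b = np.asarray(b, float)
    pi0 = pi / rho

    axes = [np.linspace(b[k] - grid_half_width, b[k] + grid_half_width, grid_n)
            for k in range(2)]
    A0, A1 = np.meshgrid(axes[0], axes[1], indexing="ij")
    alpha_grid = np.stack([A0.ravel(), A1.ravel()], axis=1)  # (G, 2)
    log_prior_alpha = -0.5 * np.sum((alpha_grid - b) ** 2 / pv, axis=1)

    lm_cache = {}
    for k in range(p + 1):
        for sub in combinations(range(p), k):
            lm_cache[sub] = log_marginal(
                y, X[:, list(sub)] if k else np.empty((len(y), 0)), g
            )

    gammas = list(product([0, 1], repeat=p))
    thetas = gammas
    psi = F @ alpha_grid.T           # (p, G)
    logq = -np.logaddexp(0.0, -psi)  # log sigmoid
    log1mq = -np.logaddexp(0.0, psi)

    pip = np.zeros(p)
    etheta = np.zeros(p)
    alpha_mean = np.zeros(2)
    total = -np.inf
    contribs = []
    for gam in gammas:
        sub = tuple(i for i in range(p) if gam[i])
        lm = lm_cache[sub]
        for th in thetas:
            lg = 0.0
            for i in range(p):
                prob = pi if th[i] else pi0
                lg += np.log(prob) if gam[i] else np.log1p(-prob)
            ltheta = np.zeros(alpha_grid.shape[0])
            for i in range(p):
                ltheta += logq[i] if th[i] else log1mq[i]
            lw = lm + lg + ltheta + log_prior_alpha  # (G,)
            contribs.append((gam, th, lw))
            total = np.logaddexp(total, logsumexp(lw))
    for gam, th, lw in contribs:
        w = np.exp(logsumexp(lw) - total)
        for i in range(p):
            if gam[i]:
                pip[i] += w
            if th[i]:
                etheta[i] += w
        wg = np.exp(lw - total)
        alpha_mean += wg @ alpha_grid
    return pip, etheta, alpha_mean
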