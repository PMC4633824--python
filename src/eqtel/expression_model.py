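"""Per-gene Bayesian variable selection with Zellner g-prior.

Model, per gene: y = X_gamma beta_gamma + eps, eps ~ N(0, sigma^2 I), with
y and the columns of X centered (the intercept is handled by centering, as
usual for g-prior formulations), beta_gamma | sigma^2 ~ N(0, g sigma^2
(X'X)^-1) and p(sigma^2) ~ 1/sigma^2. Integrating beta and sigma^2 gives
the closed-form evidence

    m(y | gamma) = Gamma(n/2) pi^(-n/2) (1+g)^(-r/2) S^(-n/2),
    S = y'y - g/(1+g) * y' P_gamma y,

where P_gamma projects onto the column space of X_gamma and r is its rank
(rank-stabilization: duplicated columns change nothing). Each SNP's
inclusion indicator gamma carries prior phi(theta) = pi^theta (pi/rho)^(1-theta),
i.e. pi for interacting-regulators and pi0 = pi/rho otherwise; the default
pi is m/e with m the expected expression-regulators per gene and e the
expected interacting-regulators among the gene's candidates.

The sampler explores the model space hierarchically: Metropolis-Hastings
moves activate/deactivate/swap whole LD blocks, and Gibbs sweeps explore the
sparse SNP configuration within active blocks by exact conditional odds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.linalg import orth
from scipy.special import expit, gammaln, logsumexp

log = logging.getLogger("eqtel")

_RANK_TOL = 1e-9


@dataclass
class GeneModelState:
    """Spike-and-slab state for one gene."""

    gamma: np.ndarray            # (p,) 0/1 inclusion indicators
    beta: np.ndarray             # effects for included SNPs (|gamma| long)
    sigma2: float
    g: float
    pi: float
    rho: float
    m: float
    M: float

    def validate(self) -> None:
        if len(self.beta) != int(self.gamma.sum()):
            raise ValueError("beta must be non-zero exactly where gamma=1")
        if self.rho < 1:
            raise ValueError("rho must be >= 1")


def phi(theta, pi: float, rho: float):
    """Inclusion prior pi^theta (pi/rho)^(1-theta).

    phi(1) = pi, phi(0) = pi/rho; fractional theta interpolates
    geometrically, which makes log E[phi(theta)] -> E[theta] log(pi) as
    rho -> infinity with pi fixed (the two-level sparsity identity).
    """
    if not (0 < pi < 1):
        raise ValueError(f"pi must be in (0, 1), got {pi}")
    if rho < 1:
        raise ValueError(f"rho must be >= 1, got {rho}")
    theta = np.asarray(theta, dtype=float)
    if np.any((theta < 0) | (theta > 1)):
        raise ValueError("theta must lie in [0, 1]")
    out = pi**theta * (pi / rho) ** (1.0 - theta)
    return float(out) if out.ndim == 0 else out


def marginal_inclusion_prior(q, pi: float, rho: float):
    """P(gamma=1) with theta summed out: q*pi + (1-q)*pi/rho.

    This exact Rao-Blackwellization over theta is what the gamma updates
    use as their prior inclusion probability.
    """
    q = np.asarray(q, dtype=float)
    out = q * pi + (1.0 - q) * (pi / rho)
    return float(out) if out.ndim == 0 else out


def _proj_norm2(y: np.ndarray, x: np.ndarray) -> tuple[float, int]:
    """(||P_x y||^2, rank(x)) via an SVD-based orthonormal basis."""
    if x.size == 0:
        return 0.0, 0
    q = orth(x, rcond=_RANK_TOL)
    u = q.T @ y
    return float(u @ u), q.shape[1]


def log_marginal(y: np.ndarray, x_gamma: np.ndarray, g: float) -> float:
    """Closed-form log evidence of y under the g-prior, beta and sigma^2 out.

    y must be centered; x_gamma columns are centered internally. Exact
    agreement with 2-D numerical integration is part of the test suite.
    Rank-deficient designs are handled by projecting onto the column space
    (with the rank, not the column count, in the dimension penalty).
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    x_gamma = np.asarray(x_gamma, dtype=float)
    if x_gamma.ndim == 1:
        x_gamma = x_gamma[:, None]
    k = 0 if x_gamma.size == 0 else x_gamma.shape[1]
    if k >= n - 2:
        raise ValueError(f"|gamma|={k} >= n-2={n - 2}")
    if k and np.linalg.matrix_rank(x_gamma, tol=None) < k:
        log.warning("rank-deficient design in log_marginal; "
                    "using rank-stabilized pseudo-solve")
    xc = x_gamma - x_gamma.mean(axis=0) if k else x_gamma
    pn2, r = _proj_norm2(y, xc)
    c = g / (1.0 + g)
    s = float(y @ y) - c * pn2
    return float(
        gammaln(n / 2.0) - (n / 2.0) * np.log(np.pi)
        - (r / 2.0) * np.log1p(g) - (n / 2.0) * np.log(s)
    )


# ---------------------------------------------------------------------------
# efficient per-gene sampler state


class GeneSampler:
    """Mutable spike-and-slab sampler state for one gene.

    Keeps the centered design, the active SNP set, an orthonormal basis of
    the active columns and the per-SNP log prior odds; provides exact
    conditional inclusion odds for every SNP (used both for Gibbs flips and
    for the Rao-Blackwellized PIP), block Metropolis-Hastings moves, and
    conditional draws of (beta, sigma^2).
    """

    def __init__(self, y, X, block_id, g=None, max_model=None):
        y = np.asarray(y, dtype=float)
        self.n = len(y)
        self.y = y - y.mean()
        X = np.asarray(X, dtype=float)
        self.X = X - X.mean(axis=0)
        self.p = self.X.shape[1]
        self.block_id = np.asarray(block_id)
        self.g = float(self.n if g is None else g)
        self.c = self.g / (1.0 + self.g)
        self.max_model = int(max_model) if max_model else max(self.n - 3, 1)
        self.yty = float(self.y @ self.y)
        self.w = self.X.T @ self.y
        self.colsq = np.einsum("ij,ij->j", self.X, self.X)
        self.blocks = {}
        for b in np.unique(self.block_id):
            self.blocks[b] = np.flatnonzero(self.block_id == b)
        self.block_keys = list(self.blocks)
        self.active: list[int] = []
        self.lpo = np.zeros(self.p)  # log prior odds per SNP
        self._refresh()

    # -- state maintenance

    def set_inclusion_prior(self, prob: np.ndarray) -> None:
        prob = np.clip(np.asarray(prob, dtype=float), 1e-300, 1 - 1e-12)
        self.lpo = np.log(prob) - np.log1p(-prob)

    def set_active(self, active) -> None:
        self.active = sorted(int(a) for a in active)
        self._refresh()

    def _refresh(self) -> None:
        if self.active:
            self.Q = orth(self.X[:, self.active], rcond=_RANK_TOL)
            u = self.Q.T @ self.y
            self._pn2 = float(u @ u)
            self._rank = self.Q.shape[1]
        else:
            self.Q = np.empty((self.n, 0))
            self._pn2 = 0.0
            self._rank = 0
        self.S = self.yty - self.c * self._pn2

    # -- evidence

    def log_marginal_rel(self, pn2: float | None = None, rank: int | None = None) -> float:
        """Evidence up to the gamma-independent constant."""
        pn2 = self._pn2 if pn2 is None else pn2
        rank = self._rank if rank is None else rank
        return float(
            -(rank / 2.0) * np.log1p(self.g)
            - (self.n / 2.0) * np.log(self.yty - self.c * pn2)
        )

    def log_posterior_rel(self) -> float:
        """Evidence + inclusion-prior mass of the current configuration."""
        act = np.zeros(self.p, dtype=bool)
        act[self.active] = True
        prior = float(self.lpo[act].sum())  # relative to the all-zero model
        return self.log_marginal_rel() + prior

    def _stats_for(self, active: list[int]) -> tuple[float, int]:
        if not active:
            return 0.0, 0
        return _proj_norm2(self.y, self.X[:, active])

    def add_gains(self, idx: np.ndarray) -> np.ndarray:
        """Delta log-evidence for adding each (inactive) SNP in idx."""
        idx = np.asarray(idx, dtype=int)
        Xi = self.X[:, idx]
        if self._rank:
            C = self.Q.T @ Xi
            u = self.Q.T @ self.y
            resid_sq = self.colsq[idx] - np.einsum("ij,ij->j", C, C)
            num = self.w[idx] - C.T @ u
        else:
            resid_sq = self.colsq[idx].copy()
            num = self.w[idx].copy()
        collinear = resid_sq <= _RANK_TOL * np.maximum(self.colsq[idx], 1.0)
        dp = np.where(collinear, 0.0, num**2 / np.where(collinear, 1.0, resid_sq))
        s_new = np.maximum(self.S - self.c * dp, 1e-300)
        gain = -(self.n / 2.0) * (np.log(s_new) - np.log(self.S))
        gain -= np.where(collinear, 0.0, 0.5 * np.log1p(self.g))
        return gain

    def drop_gain(self, j: int) -> float:
        """Delta log-evidence for removing active SNP j."""
        rest = [a for a in self.active if a != j]
        pn2, rank = self._stats_for(rest)
        return self.log_marginal_rel(pn2, rank) - self.log_marginal_rel()

    def conditional_inclusion(self) -> np.ndarray:
        """Exact P(gamma_i=1 | gamma_-i, y, priors) for every SNP.

        These conditionals drive the Gibbs flips and, averaged over
        iterations, form the Rao-Blackwellized PIP.
        """
        logodds = np.empty(self.p)
        inactive = np.ones(self.p, dtype=bool)
        inactive[self.active] = False
        ii = np.flatnonzero(inactive)
        if len(self.active) >= self.max_model:
            logodds[ii] = -np.inf  # adding would exceed the model-size cap
        else:
            logodds[ii] = self.add_gains(ii) + self.lpo[ii]
        for j in self.active:
            logodds[j] = -self.drop_gain(j) + self.lpo[j]
        with np.errstate(over="ignore"):
            return expit(logodds)

    # -- Gibbs within blocks

    def gibbs_sweep(self, rng: np.random.Generator, snps=None) -> None:
        """Sequential exact-conditional flips over SNPs of active blocks."""
        if snps is None:
            active_blocks = {self.block_id[a] for a in self.active}
            snps = [s for b in active_blocks for s in self.blocks[b]]
        snps = list(snps)
        rng.shuffle(snps)
        for i in snps:
            i = int(i)
            if i in self.active:
                lo = -self.drop_gain(i) + self.lpo[i]
                if rng.uniform() >= expit(lo):  # drop
                    self.active.remove(i)
                    self._refresh()
            else:
                if len(self.active) >= self.max_model:
                    continue
                gain = float(self.add_gains(np.array([i]))[0])
                lo = gain + self.lpo[i]
                if rng.uniform() < expit(lo):
                    self.active.append(i)
                    self._refresh()

    # -- block-level Metropolis-Hastings

    def _softmax_pick(self, idx: np.ndarray, rng) -> tuple[int, float]:
        """Pick a SNP within a block by softmax of conditional log-odds."""
        ell = self.add_gains(idx) + self.lpo[idx]
        ell = ell - ell.max()
        prob = np.exp(ell)
        prob /= prob.sum()
        k = rng.choice(len(idx), p=prob)
        return int(idx[k]), float(np.log(prob[k]))

    def _softmax_logprob(self, idx: np.ndarray, snp: int) -> float:
        ell = self.add_gains(idx) + self.lpo[idx]
        ell = ell - ell.max()
        prob = np.exp(ell)
        prob /= prob.sum()
        return float(np.log(prob[np.flatnonzero(idx == snp)[0]]))

    def _block_census(self):
        counts = {}
        for a in self.active:
            counts[self.block_id[a]] = counts.get(self.block_id[a], 0) + 1
        inactive = [b for b in self.block_keys if b not in counts]
        single = [b for b, cnt in counts.items() if cnt == 1]
        return counts, inactive, single

    def block_move(self, rng: np.random.Generator,
                   mix=(0.4, 0.4, 0.2)) -> None:
        """One MH proposal at the LD-block level.

        Activation adds a single SNP drawn from a within-block softmax of
        conditional log-odds; deactivation removes the SNP of a
        single-SNP block; swap combines the two. Acceptance uses exact
        evidence and prior ratios with the full proposal correction, so the
        chain leaves the per-gene posterior invariant (multi-SNP
        configurations are handled by the within-block Gibbs sweeps).
        """
        move = rng.choice(3, p=list(mix))
        counts, inactive, single = self._block_census()
        p_add, p_rem, _ = mix
        if move == 0:  # activate
            if not inactive or len(self.active) >= self.max_model:
                return
            b = inactive[rng.integers(len(inactive))]
            idx = self.blocks[b]
            s, logq = self._softmax_pick(idx, rng)
            gain = float(self.add_gains(np.array([s]))[0])
            dpost = gain + self.lpo[s]
            n1_new = len(single) + 1
            loga = dpost + np.log(p_rem / n1_new) - (
                np.log(p_add) - np.log(len(inactive)) + logq
            )
            if np.log(rng.uniform()) < loga:
                self.active.append(s)
                self._refresh()
        elif move == 1:  # deactivate a single-SNP block
            if not single:
                return
            b = single[rng.integers(len(single))]
            s = int(next(a for a in self.active if self.block_id[a] == b))
            dpost = self.drop_gain(s) - self.lpo[s]
            rest = [a for a in self.active if a != s]
            saved = self.active
            self.set_active(rest)
            logq_rev = self._softmax_logprob(self.blocks[b], s)
            n_inact_new = len(inactive) + 1
            loga = dpost + (
                np.log(p_add) - np.log(n_inact_new) + logq_rev
            ) - np.log(p_rem / len(single))
            if np.log(rng.uniform()) < loga:
                return  # accepted: stay at the reduced state
            self.set_active(saved)
        else:  # swap: drop one single-SNP block, activate an inactive one
            if not single or not inactive:
                return
            b1 = single[rng.integers(len(single))]
            s1 = int(next(a for a in self.active if self.block_id[a] == b1))
            b2 = inactive[rng.integers(len(inactive))]
            saved = self.active
            lp_old = self.log_posterior_rel()
            mid = [a for a in self.active if a != s1]
            self.set_active(mid)
            s2, logq_fwd = self._softmax_pick(self.blocks[b2], rng)
            logq_rev = self._softmax_logprob(self.blocks[b1], s1)
            self.set_active(mid + [s2])
            lp_new = self.log_posterior_rel()
            counts2, inactive2, single2 = self._block_census()
            loga = (lp_new - lp_old) + (
                -np.log(len(single2)) - np.log(len(inactive2)) + logq_rev
            ) - (-np.log(len(single)) - np.log(len(inactive)) + logq_fwd)
            if np.log(rng.uniform()) < loga:
                return
            self.set_active(saved)

    # -- conditional draws

    def beta_ls(self) -> np.ndarray:
        if not self.active:
            return np.empty(0)
        Xa = self.X[:, self.active]
        return np.linalg.lstsq(Xa, self.y, rcond=_RANK_TOL)[0]

    def sample_effects(self, rng: np.random.Generator) -> tuple[np.ndarray, float]:
        """(beta, sigma^2) from their exact conditionals given gamma."""
        sigma2 = (self.S / 2.0) / rng.gamma(self.n / 2.0)
        if not self.active:
            return np.empty(0), float(sigma2)
        Xa = self.X[:, self.active]
        G = Xa.T @ Xa
        bls = np.linalg.lstsq(Xa, self.y, rcond=_RANK_TOL)[0]
        mean = self.c * bls
        cov = sigma2 * self.c * np.linalg.pinv(G, rcond=_RANK_TOL)
        beta = rng.multivariate_normal(mean, cov, method="svd")
        return beta, float(sigma2)

    def posterior_mean_effects(self) -> np.ndarray:
        """E[beta | gamma, y] = g/(1+g) * beta_LS, embedded at full length."""
        out = np.zeros(self.p)
        if self.active:
            out[self.active] = self.c * self.beta_ls()
        return out


# ---------------------------------------------------------------------------
# functional operation surface


def gamma_gibbs_step(y, x_block, gamma, priors, g, rng,
                     block_id=None) -> np.ndarray:
    """One random-order Gibbs sweep with exact conditional flip odds.

    ``priors`` are per-SNP inclusion prior probabilities (phi values).
    Returns the updated gamma vector.
    """
    X = np.asarray(x_block, dtype=float)
    gs = GeneSampler(y, X, np.zeros(X.shape[1], int) if block_id is None else block_id,
                     g=g)
    gs.set_inclusion_prior(np.asarray(priors, dtype=float))
    gs.set_active(np.flatnonzero(np.asarray(gamma) == 1))
    gs.gibbs_sweep(rng, snps=range(X.shape[1]))
    out = np.zeros(X.shape[1])
    out[gs.active] = 1.0
    return out


def block_move(y, X, block_id, gamma, priors, g, rng,
               n_moves: int = 1) -> np.ndarray:
    """Block-level MH move(s) on gamma; returns the updated gamma vector."""
    gs = GeneSampler(y, X, block_id, g=g)
    gs.set_inclusion_prior(np.asarray(priors, dtype=float))
    gs.set_active(np.flatnonzero(np.asarray(gamma) == 1))
    for _ in range(n_moves):
        gs.block_move(rng)
    out = np.zeros(X.shape[1])
    out[gs.active] = 1.0
    return out


def sample_pi(
    gamma: np.ndarray,
    theta: np.ndarray,
    m: float,
    M: float,
    e: float,
    rho: float,
    rng: np.random.Generator,
    mode: str = "fixed",
    grid: int = 2048,
) -> float:
    """Draw pi from its conditional on the truncated uniform support (m/e, M/e).

    In "fixed" mode (the default) returns m/e. In "sampled" mode the
    conditional density over the support is evaluated on a grid and sampled
    by inverse CDF with within-cell jitter.
    """
    lo, hi = m / e, M / e
    if mode == "fixed":
        return float(lo)
    if not m < M:
        raise ValueError(f"need m < M in sampled mode (m={m}, M={M})")
    if hi >= 1:
        raise ValueError("M/e must be < 1")
    gamma = np.asarray(gamma, dtype=float)
    theta = np.asarray(theta, dtype=float)
    edges = np.linspace(lo, hi, grid + 1)
    pis = 0.5 * (edges[:-1] + edges[1:])
    n11 = float(((theta == 1) & (gamma == 1)).sum())
    n10 = float(((theta == 1) & (gamma == 0)).sum())
    n01 = float(((theta == 0) & (gamma == 1)).sum())
    n00 = float(((theta == 0) & (gamma == 0)).sum())
    loglik = (
        n11 * np.log(pis)
        + n10 * np.log1p(-pis)
        + n01 * np.log(pis / rho)
        + n00 * np.log1p(-pis / rho)
    )
    w = np.exp(loglik - loglik.max())
    w /= w.sum()
    cell = rng.choice(grid, p=w)
    return float(rng.uniform(edges[cell], edges[cell + 1]))


def sample_beta_sigma(y, x_gamma, g, rng) -> tuple[np.ndarray, float]:
    """Conjugate conditional draw of (beta, sigma^2) for a fixed gamma.

    sigma^2 is inverse-gamma; beta is normal with mean g/(1+g) times the
    least-squares solution and covariance sigma^2 g/(1+g) (X'X)^-1.
    """
    X = np.asarray(x_gamma, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.size == 0:
        X = np.empty((len(y), 0))
    gs = GeneSampler(y, X, np.zeros(X.shape[1], int), g=g)
    gs.set_active(range(X.shape[1]))
    return gs.sample_effects(rng)


def predict(
    x_new: np.ndarray,
    draws: list[tuple[np.ndarray, np.ndarray]],
    train_mean: np.ndarray,
    train_y_mean: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior-mean prediction averaged over retained (gamma, beta) draws.

    ``draws`` holds (active index array, beta) pairs on the training
    centering; ``train_mean`` are the training column means. Returns
    (mean_prediction, per-draw predictions).
    """
    if not draws:
        raise ValueError("need >= 1 retained posterior draw")
    Xc = np.asarray(x_new, dtype=float) - np.asarray(train_mean, dtype=float)
    per = np.empty((len(draws), Xc.shape[0]))
    for d, (idx, beta) in enumerate(draws):
        idx = np.asarray(idx, dtype=int)
        per[d] = Xc[:, idx] @ beta + train_y_mean if len(idx) else train_y_mean
    return per.mean(axis=0), per


def enumerate_posterior(
    y: np.ndarray,
    X: np.ndarray,
    prior_incl: np.ndarray,
    g: float,
    max_size: int | None = None,
) -> tuple[np.ndarray, dict]:
    """Exact posterior inclusion probabilities by full model enumeration.

    Feasible for p <= ~16; serves as the ground truth the MCMC sampler is
    validated against on small instances.
    """
    y = np.asarray(y, dtype=float)
    y = y - y.mean()
    X = np.asarray(X, dtype=float)
    p = X.shape[1]
    if p > 16:
        raise ValueError("enumeration limited to p <= 16")
    prior_incl = np.asarray(prior_incl, dtype=float)
    lp_in = np.log(prior_incl)
    lp_out = np.log1p(-prior_incl)
    max_size = max_size or (len(y) - 3)
    configs, weights = [], []
    for k in range(0, min(p, max_size) + 1):
        for subset in combinations(range(p), k):
            lm = log_marginal(y, X[:, list(subset)] if k else np.empty((len(y), 0)), g)
            lprior = lp_in[list(subset)].sum() + lp_out.sum() - lp_out[list(subset)].sum()
            configs.append(subset)
            weights.append(lm + lprior)
    weights = np.array(weights)
    wnorm = np.exp(weights - logsumexp(weights))
    pip = np.zeros(p)
    for cfg, w in zip(configs, wnorm):
        for i in cfg:
            pip[i] += w
    return pip, {"configs": configs, "weights": wnorm}
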