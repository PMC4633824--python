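"""Bayesian logistic regression for regulatory-interaction potential.

Each candidate SNP-gene pair carries a latent indicator theta (is the SNP an
interacting-regulator for that gene?). The probability q = logistic(alpha.F)
is the pair's prior potential, a function of the SNP's epigenetic features
and the pair's interaction features (F includes a leading bias entry). The
weights alpha are shared genome-wide and get a normal prior centred at b,
all zeros except the bias prior b0 = log(e / (p - e)) which encodes the
expected interacting-regulator fraction (b0 = log(1/99) at 1%).

Given the expression model's current inclusion indicators gamma, theta has
the exact conditional

    P(theta=1 | gamma, alpha) = q B(gamma; pi) / [q B(gamma; pi) + (1-q) B(gamma; pi0)]

with B(g; x) = x^g (1-x)^(1-g) and pi0 = pi/rho; this Rao-Blackwellized
quantity is both the reported potential theta_hat and the basis of the
semi-supervised clustering of SNPs into regulators and non-regulators.
alpha is drawn from its exact conditional via Polya-Gamma augmentation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from eqtel.polya_gamma import polya_gamma

log = logging.getLogger("eqtel")


@dataclass
class RegulatoryState:
    alpha: np.ndarray            # (d,) weights, alpha[0] is the bias
    b: np.ndarray                # (d,) prior mean, zeros except b[0]
    prior_var: np.ndarray        # (d,) prior variances
    theta: np.ndarray            # (n_pairs,) current indicators
    theta_hat: np.ndarray        # (n_pairs,) Rao-Blackwellized P(theta=1)
    e: float                     # expected number of interacting-regulators

    @classmethod
    def initial(
        cls,
        n_pairs: int,
        n_features: int,
        regulator_fraction: float = 0.01,
        prior_var: float = 1.0,
    ) -> "RegulatoryState":
        e = regulator_fraction * n_pairs
        b = np.zeros(n_features)
        b[0] = np.log(e / (n_pairs - e))
        q0 = expit(b[0])
        return cls(
            alpha=b.copy(),
            b=b,
            prior_var=np.full(n_features, float(prior_var)),
            theta=np.zeros(n_pairs),
            theta_hat=np.full(n_pairs, q0),
            e=e,
        )


def potential(alpha: np.ndarray, f: np.ndarray) -> np.ndarray | float:
    """Regulatory-interaction potential logistic(alpha . f).

    ``f`` may be a single feature vector (with leading 1 bias entry) or a
    matrix of rows of such vectors.
    """
    f = np.asarray(f, dtype=float)
    if not np.all(np.isfinite(f)):
        raise ValueError("non-finite feature value")
    out = expit(f @ np.asarray(alpha, dtype=float))
    return float(out) if out.ndim == 0 else out


def _check_args(q, pi: float, rho: float) -> None:
    if not (0 < pi < 1):
        raise ValueError(f"pi must be in (0, 1), got {pi}")
    if rho < 1:
        raise ValueError(f"rho must be >= 1, got {rho}")
    if pi / rho >= 1:
        raise ValueError(f"pi/rho must be < 1 (pi={pi}, rho={rho})")


def theta_posterior(gamma, q, pi: float, rho: float):
    """Exact P(theta=1 | gamma, alpha) by Bayes rule.

    q is the prior potential logistic(alpha.F); gamma's likelihood under
    theta=1 is Bernoulli(pi), under theta=0 Bernoulli(pi0=pi/rho). At q=0
    or q=1 the prior is decisive. Vectorized over pairs.
    """
    _check_args(q, pi, rho)
    gamma = np.asarray(gamma, dtype=float)
    q = np.asarray(q, dtype=float)
    pi0 = pi / rho
    lik1 = np.where(gamma == 1, pi, 1.0 - pi)
    lik0 = np.where(gamma == 1, pi0, 1.0 - pi0)
    num = q * lik1
    den = num + (1.0 - q) * lik0
    out = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return float(out) if out.ndim == 0 else out


def sample_theta(gamma, q, pi: float, rho: float, rng: np.random.Generator):
    """Bernoulli draw of theta from its exact conditional."""
    prob = theta_posterior(gamma, q, pi, rho)
    draw = rng.uniform(size=np.shape(prob) or None) < prob
    return np.asarray(draw, dtype=float) if np.ndim(prob) else float(draw)


def sample_alpha(
    f_matrix: np.ndarray,
    theta: np.ndarray,
    b: np.ndarray,
    prior_var: np.ndarray | float,
    rng: np.random.Generator,
    alpha_current: np.ndarray | None = None,
    n_sweeps: int = 1,
) -> np.ndarray:
    """One Gibbs draw of alpha given theta labels via Polya-Gamma augmentation.

    Model: theta_i ~ Bern(logistic(f_i . alpha)), alpha ~ N(b, diag(prior_var)).
    Each sweep draws omega_i ~ PG(1, f_i . alpha) then alpha from its normal
    conditional; repeated calls form a chain with the correct stationary
    distribution. The proper prior keeps the draw defined even under complete
    separation (a warning is logged).
    """
    F = np.asarray(f_matrix, dtype=float)
    theta = np.asarray(theta, dtype=float)
    b = np.asarray(b, dtype=float)
    d = F.shape[1]
    pv = np.broadcast_to(np.asarray(prior_var, dtype=float), (d,)).copy()
    if np.any(pv < 0):
        raise ValueError("prior_var must be >= 0")
    if theta.min() == theta.max() and len(theta) > 1:
        log.warning("all theta labels identical (%g); possible separability",
                    theta.min())
    if np.all(pv == 0):
        return b.copy()
    alpha = b.copy() if alpha_current is None else np.asarray(alpha_current, float).copy()
    prior_prec = np.where(pv > 0, 1.0 / np.where(pv > 0, pv, 1.0), 1e12)
    kappa = theta - 0.5
    Fk = F.T @ kappa
    for _ in range(n_sweeps):
        psi = F @ alpha
        omega = polya_gamma(psi, rng)
        prec = (F.T * omega) @ F
        prec[np.diag_indices(d)] += prior_prec
        L = np.linalg.cholesky(prec)
        mean = np.linalg.solve(prec, Fk + prior_prec * b)
        z = rng.standard_normal(d)
        alpha = mean + np.linalg.solve(L.T, z)
    return alpha


def sample_alpha_spike_slab(
    f_matrix: np.ndarray,
    theta: np.ndarray,
    b: np.ndarray,
    prior_var: np.ndarray | float,
    rng: np.random.Generator,
    alpha_current: np.ndarray | None = None,
    inclusion_prior: float = 0.5,
    indicators: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Optional feature selection: spike-and-slab indicators on alpha.

    Conditional on the Polya-Gamma draws the logistic model is linear-
    Gaussian, so each non-bias weight gets a point-mass-at-zero spike vs a
    N(b_k, prior_var_k) slab, flipped by its exact conditional odds; the
    bias is always included. Returns (alpha draw, indicator vector). Off by
    default in the coupled sampler (``EqtelConfig.alpha_selection``).
    """
    F = np.asarray(f_matrix, dtype=float)
    theta = np.asarray(theta, dtype=float)
    b = np.asarray(b, dtype=float)
    d = F.shape[1]
    pv = np.broadcast_to(np.asarray(prior_var, dtype=float), (d,)).copy()
    alpha = b.copy() if alpha_current is None else np.asarray(alpha_current, float).copy()
    if indicators is None:
        indicators = np.ones(d, dtype=bool)
    indicators = indicators.copy()
    indicators[0] = True
    kappa = theta - 0.5
    psi = F @ alpha
    omega = polya_gamma(psi, rng)
    z = kappa / omega  # pseudo-data: z ~ N(F alpha, diag(1/omega))

    prior_prec = np.where(pv > 0, 1.0 / np.where(pv > 0, pv, 1.0), 1e12)

    def gauss_logml(idx):
        Fi = F[:, idx]
        prec = (Fi.T * omega) @ Fi + np.diag(prior_prec[idx])
        rhs = Fi.T @ (omega * z) + prior_prec[idx] * b[idx]
        L = np.linalg.cholesky(prec)
        mean = np.linalg.solve(prec, rhs)
        # log marginal of z given inclusion set (up to shared constants)
        return (
            -np.log(np.diag(L)).sum()
            + 0.5 * float(rhs @ mean)
            + 0.5 * np.log(prior_prec[idx]).sum()
        )

    lo_prior = np.log(inclusion_prior) - np.log1p(-inclusion_prior)
    for k in rng.permutation(np.arange(1, d)):
        with_k = indicators.copy()
        with_k[k] = True
        without_k = indicators.copy()
        without_k[k] = False
        lo = gauss_logml(np.flatnonzero(with_k)) - \
            gauss_logml(np.flatnonzero(without_k)) + lo_prior
        indicators[k] = rng.uniform() < expit(lo)
    idx = np.flatnonzero(indicators)
    Fi = F[:, idx]
    prec = (Fi.T * omega) @ Fi + np.diag(prior_prec[idx])
    mean = np.linalg.solve(prec, Fi.T @ (omega * z) + prior_prec[idx] * b[idx])
    L = np.linalg.cholesky(prec)
    draw = mean + np.linalg.solve(L.T, rng.standard_normal(len(idx)))
    alpha = np.zeros(d)
    alpha[idx] = draw
    return alpha, indicators


def rank_features(
    alpha_draws: np.ndarray, feature_names: list[str]
) -> pd.DataFrame:
    """Order features by posterior |mean|/sd (ties broken by name).

    Requires >= 100 retained draws. Near-duplicate importance between highly
    correlated draw columns triggers a collinearity warning.
    """
    draws = np.asarray(alpha_draws, dtype=float)
    if draws.shape[0] < 100:
        raise ValueError(
            f"only {draws.shape[0]} retained draws; run the sampler longer "
            "(>= 100 needed for stable feature ranking)"
        )
    mean = draws.mean(axis=0)
    sd = draws.std(axis=0, ddof=1)
    importance = np.abs(mean) / np.where(sd > 0, sd, np.inf)
    df = pd.DataFrame(
        {"feature": feature_names, "alpha_mean": mean, "alpha_sd": sd,
         "importance": importance}
    )
    if draws.shape[1] > 1:
        corr = np.corrcoef(draws.T)
        np.fill_diagonal(corr, 0.0)
        if np.nanmax(np.abs(corr)) > 0.95:
            log.warning("highly correlated posterior draws between features; "
                        "collinear feature columns suspected")
    return df.sort_values(["importance", "feature"],
                          ascending=[False, True]).reset_index(drop=True)
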