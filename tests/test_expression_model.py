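import numpy as np
import pytest
from scipy import integrate

from eqtel.expression_model import (
    GeneSampler,
    block_move,
    enumerate_posterior,
    gamma_gibbs_step,
    log_marginal,
    marginal_inclusion_prior,
    phi,
    predict,
    sample_beta_sigma,
    sample_pi,
)
from tests.oracles import enumerate_gamma_posterior


class TestPhi:
    def test_endpoints(self):
        assert phi(1, 0.01, 100.0) == pytest.approx(0.01)
        assert phi(0, 0.01, 100.0) == pytest.approx(1e-4)

    def test_geometric_interpolation(self):
        assert phi(0.5, 0.01, 100.0) == pytest.approx(1e-3, rel=1e-12)

    def test_domain(self):
        with pytest.raises(ValueError):
            phi(0.5, 1.2, 100.0)
        with pytest.raises(ValueError):
            phi(1.5, 0.1, 100.0)

    @pytest.mark.parametrize("etheta", [0.1, 0.5, 0.9])
    def test_two_level_sparsity_factorizes(self, etheta):
        """Overall sparsity is the product of the two fractions:
        E[phi(theta)] -> E[theta] * pi as rho -> infinity with pi fixed."""
        pi = 0.01
        errs = []
        for rho in (1e2, 1e4, 1e6):
            ephi = etheta * phi(1, pi, rho) + (1 - etheta) * phi(0, pi, rho)
            errs.append(abs(np.log(ephi) - np.log(etheta * pi)))
        assert errs == sorted(errs, reverse=True)  # monotone approach
        assert errs[-1] < 1e-4


class TestLogMarginal:
    def test_null_model_closed_form(self):
        y = np.array([1.0, -1.0, 2.0, -2.0, 0.5, -0.5])
        y = y - y.mean()
        from scipy.special import gammaln

        n = len(y)
        expected = gammaln(n / 2) - n / 2 * np.log(np.pi) - n / 2 * np.log(y @ y)
        assert log_marginal(y, np.empty((n, 0)), g=6.0) == pytest.approx(expected)

    def test_matches_quadrature(self):
        rng = np.random.default_rng(1)
        n = 8
        y = rng.normal(size=n)
        y = y - y.mean()
        x = rng.normal(size=n)
        g = float(n)
        lm = log_marginal(y, x, g)
        xc = x - x.mean()
        xtx = xc @ xc

        def integrand(b, s2):
            r = y - xc * b
            return (
                (2 * np.pi * s2) ** (-n / 2)
                * np.exp(-r @ r / (2 * s2))
                * np.sqrt(xtx / (2 * np.pi * g * s2))
                * np.exp(-xtx * b * b / (2 * g * s2))
                / s2
            )

        val, err = integrate.dblquad(integrand, 1e-4, 80, -15, 15,
                                     epsabs=1e-14, epsrel=1e-10)
        assert np.exp(lm) == pytest.approx(val, rel=1e-6)

    def test_duplicate_column_invariant(self):
        rng = np.random.default_rng(2)
        y = rng.normal(size=12)
        x = rng.normal(size=12)
        a = log_marginal(y, x, g=12.0)
        b = log_marginal(y, np.column_stack([x, x]), g=12.0)
        assert a == pytest.approx(b, abs=1e-8)

    def test_too_many_predictors(self):
        rng = np.random.default_rng(3)
        with pytest.raises(ValueError, match="n-2"):
            log_marginal(rng.normal(size=5), rng.normal(size=(5, 4)), g=5.0)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(4)
        n, p = 15, 3
        y = rng.normal(size=n)
        X = rng.normal(size=(n, p))
        base = log_marginal(y, X, g=float(n))
        perm = rng.permutation(n)
        assert log_marginal(y[perm], X[perm], g=float(n)) == pytest.approx(base)
        cperm = rng.permutation(p)
        assert log_marginal(y, X[:, cperm], g=float(n)) == pytest.approx(base)


class TestGibbs:
    def test_zero_prior_never_included(self, rng):
        n, p = 30, 4
        X = rng.standard_normal((n, p))
        y = X[:, 0] + 0.1 * rng.standard_normal(n)
        priors = np.array([0.5, 0.5, 1e-300, 0.5])
        gam = np.zeros(p)
        for _ in range(50):
            gam = gamma_gibbs_step(y, X, gam, priors, g=float(n), rng=rng)
            assert gam[2] == 0

    def test_correlated_pair_mass_splits_or_concentrates(self, rng):
        """Two near-copies of the causal SNP: equal phi splits posterior mass;
        a 10x larger phi on one concentrates it there (2-SNP enumeration)."""
        n = 60
        z = rng.standard_normal(n)
        X = np.column_stack([z, z])  # perfectly correlated pair
        y = z + 0.5 * rng.standard_normal(n)
        pip_eq = enumerate_gamma_posterior(y, X, np.array([0.1, 0.1]), g=float(n))
        assert pip_eq[0] == pytest.approx(pip_eq[1], abs=1e-10)  # mass shared
        pip_biased = enumerate_gamma_posterior(
            y, X, np.array([0.5, 0.05]), g=float(n)
        )
        assert pip_biased[0] > pip_biased[1] + 0.4
        # sampler agrees with the enumeration
        gs = GeneSampler(y, X, np.zeros(2, int), g=float(n))
        gs.set_inclusion_prior(np.array([0.5, 0.05]))
        acc = np.zeros(2)
        for t in range(3000):
            gs.gibbs_sweep(rng, snps=range(2))
            if t >= 500:
                acc += gs.conditional_inclusion()
        np.testing.assert_allclose(acc / 2500, pip_biased, atol=0.02)

    def test_null_inclusion_matches_prior_mass(self, rng):
        n, p = 50, 20
        X = rng.standard_normal((n, p))
        y = rng.standard_normal(n)
        priors = np.full(p, 0.01)
        gs = GeneSampler(y, X, np.zeros(p, int), g=float(n))
        gs.set_inclusion_prior(priors)
        count = []
        for t in range(3000):
            gs.gibbs_sweep(rng, snps=range(p))
            count.append(len(gs.active))
        mean_incl = np.mean(count[500:])
        # null data: expected included about sum(phi), generous MC band
        assert abs(mean_incl - priors.sum()) < 0.15


class TestBlockMove:
    def test_single_block_two_model_posterior(self, rng):
        n = 40
        x = rng.standard_normal(n)
        y = 0.8 * x + rng.standard_normal(n)
        X = x[:, None]
        prior = np.array([0.3])
        pip_exact = enumerate_gamma_posterior(y, X, prior, g=float(n))
        gs = GeneSampler(y, X, np.zeros(1, int), g=float(n))
        gs.set_inclusion_prior(prior)
        occ = []
        for t in range(12000):
            gs.block_move(rng)
            occ.append(len(gs.active))
        freq = np.mean(occ[2000:])
        assert freq == pytest.approx(pip_exact[0], abs=0.03)

    def test_two_block_decoy_instance(self, rng):
        """Causal SNP in block A, independent decoy in block B: exact
        16-configuration posterior puts more occupancy on A; the block
        sampler reproduces the exact PIPs."""
        n = 50
        X = rng.standard_normal((n, 4))
        y = 1.0 * X[:, 0] + rng.standard_normal(n)
        blocks = np.array([0, 0, 1, 1])
        prior = np.full(4, 0.2)
        pip_exact = enumerate_gamma_posterior(y, X, prior, g=float(n))
        assert pip_exact[0] > max(pip_exact[2], pip_exact[3])
        gs = GeneSampler(y, X, blocks, g=float(n))
        gs.set_inclusion_prior(prior)
        acc = np.zeros(4)
        nit, burn = 12000, 2000
        for t in range(nit):
            gs.block_move(rng)
            gs.gibbs_sweep(rng)
            if t >= burn:
                acc += gs.conditional_inclusion()
        np.testing.assert_allclose(acc / (nit - burn), pip_exact, atol=0.03)

    def test_functional_wrapper_runs(self, rng):
        n = 30
        X = rng.standard_normal((n, 4))
        y = rng.standard_normal(n)
        gam = block_move(y, X, np.array([0, 0, 1, 1]), np.zeros(4),
                         np.full(4, 0.1), float(n), rng, n_moves=10)
        assert set(np.unique(gam)) <= {0.0, 1.0}


class TestSamplePi:
    def test_fixed_mode_ratio(self):
        rng = np.random.default_rng(0)
        assert sample_pi(np.zeros(0), np.zeros(0), 2.0, 10.0, 200.0, 100.0,
                         rng, mode="fixed") == pytest.approx(0.01)

    def test_prior_sampling_uniform(self, rng):
        from scipy import stats

        draws = [
            sample_pi(np.zeros(0), np.zeros(0), 2.0, 10.0, 200.0, 100.0,
                      rng, mode="sampled")
            for _ in range(2000)
        ]
        u = (np.array(draws) - 0.01) / (0.05 - 0.01)
        assert stats.kstest(u, "uniform").pvalue > 0.01

    def test_posterior_respects_truncation(self, rng):
        # strong data favouring pi ~ 0.01 inside support (0.005, 0.02)
        gamma = np.r_[np.ones(10), np.zeros(990)]
        theta = np.r_[np.ones(1000)]
        draws = [
            sample_pi(gamma, theta, 1.0, 4.0, 200.0, 100.0, rng, mode="sampled")
            for _ in range(300)
        ]
        assert 0.005 < np.mean(draws) < 0.02
        assert np.min(draws) >= 0.005 and np.max(draws) <= 0.02

    def test_sampled_mode_requires_m_lt_M(self, rng):
        with pytest.raises(ValueError, match="m < M"):
            sample_pi(np.zeros(0), np.zeros(0), 5.0, 5.0, 200.0, 100.0,
                      rng, mode="sampled")


class TestSampleBetaSigma:
    def test_posterior_mean_shrinkage(self, rng):
        n = 40
        X = rng.standard_normal((n, 2))
        y = X @ np.array([1.0, -0.5]) + rng.standard_normal(n)
        g = float(n)
        yc = y - y.mean()
        Xc = X - X.mean(axis=0)
        bls = np.linalg.lstsq(Xc, yc, rcond=None)[0]
        target = g / (1 + g) * bls
        draws = np.array([sample_beta_sigma(y, X, g, rng)[0] for _ in range(8000)])
        se = draws.std(axis=0) / np.sqrt(len(draws)) * 4 + 1e-3
        np.testing.assert_allclose(draws.mean(axis=0), target, atol=se.max())

    def test_large_g_approaches_least_squares(self, rng):
        n = 30
        X = rng.standard_normal((n, 1))
        y = 2.0 * X[:, 0] + 0.1 * rng.standard_normal(n)
        yc = y - y.mean()
        Xc = X - X.mean(axis=0)
        bls = np.linalg.lstsq(Xc, yc, rcond=None)[0]
        draws = np.array(
            [sample_beta_sigma(y, X, 1e12, rng)[0][0] for _ in range(2000)]
        )
        assert draws.mean() == pytest.approx(bls[0], abs=0.01)

    def test_empty_gamma(self, rng):
        y = rng.standard_normal(20)
        beta, s2 = sample_beta_sigma(y, np.empty((20, 0)), 20.0, rng)
        assert beta.size == 0 and s2 > 0


class TestPredict:
    def test_noiseless_recovery(self, rng):
        n, p = 80, 5
        X = rng.standard_normal((n, p))
        beta = np.array([1.0, -2.0, 0.0, 0.0, 0.5])
        y = X @ beta
        draws = [(np.array([0, 1, 4]), beta[[0, 1, 4]])]
        mean, per = predict(X, draws, X.mean(axis=0), float(y.mean()))
        assert np.corrcoef(mean, y)[0, 1] > 0.99
        assert per.shape == (1, n)

    def test_empty_draws_error(self):
        with pytest.raises(ValueError, match="retained"):
            predict(np.zeros((3, 2)), [], np.zeros(2))

    def test_all_zero_gamma_constant_prediction(self):
        X = np.random.default_rng(0).normal(size=(10, 3))
        mean, _ = predict(X, [(np.array([], dtype=int), np.empty(0))],
                          X.mean(axis=0), 0.0)
        assert np.allclose(mean, 0.0)


def test_marginal_inclusion_prior_mixture():
    # exact theta marginalization: q*pi + (1-q)*pi0
    assert marginal_inclusion_prior(0.5, 0.01, 100.0) == pytest.approx(
        0.5 * 0.01 + 0.5 * 1e-4
    )
    assert marginal_inclusion_prior(1.0, 0.01, 100.0) == pytest.approx(0.01)


def test_enumeration_agreement_between_implementations(rng):
    """Package enumeration and the independent oracle agree exactly."""
    n, p = 25, 5
    X = rng.standard_normal((n, p))
    y = X[:, 1] * 0.8 + rng.standard_normal(n)
    prior = rng.uniform(0.05, 0.3, size=p)
    a, _ = enumerate_posterior(y, X, prior, g=float(n))
    b = enumerate_gamma_posterior(y, X, prior, g=float(n))
    np.testing.assert_allclose(a, b, atol=1e-10)
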