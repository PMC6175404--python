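import math

import numpy as np
import pytest
from scipy.integrate import dblquad
from scipy.stats import gamma as gamma_dist
from scipy.stats import kstest

from pairsel import (PairedDesign, acceptance_probability,
                     integrated_log_marginal, update_coefficients,
                     update_variance_scales)
from pairsel.model import (CoefficientState, ModelConfiguration, PriorSpec)
from pairsel.sampler import (BIRTH_SINGLETON, AugmentationState, MoveProposal,
                             _GaussSystem, _AugCache)


def _aug(z, lam):
    return AugmentationState(np.asarray(z, float), np.asarray(lam, float))


class TestIntegratedLogMarginal:
    def test_intercept_only_degenerate_prior_limit(self):
        """With the intercept prior collapsed to zero, the marginal of a
        single z=0, lambda=1 observation is the standard normal density."""
        d = PairedDesign(np.array([1]), np.zeros((1, 1)), np.zeros((1, 1)))
        prior = PriorSpec(intercept_sd=1e-8, kmax=1)
        val = integrated_log_marginal(ModelConfiguration(), _aug([0.0], [1.0]),
                                      d, prior, 1.0, 1.0)
        assert val == pytest.approx(-0.5 * math.log(2 * math.pi), abs=1e-9)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(8)
        n, p = 12, 4
        d = PairedDesign(np.zeros(n, dtype=int), rng.normal(size=(n, p)),
                         rng.normal(size=(n, p)))
        aug = _aug(rng.normal(size=n), rng.gamma(2, 1, n))
        prior = PriorSpec(kmax=4)
        v1 = integrated_log_marginal(ModelConfiguration((0, 2, 3), (1,)), aug,
                                     d, prior, 1.3, 0.7)
        v2 = integrated_log_marginal(ModelConfiguration((3, 0, 2), (1,)), aug,
                                     d, prior, 1.3, 0.7)
        assert v1 == pytest.approx(v2, rel=1e-12)

    def test_against_2d_quadrature(self):
        """n=5, one singleton: the Cholesky-identity value must agree with
        direct 2-D numerical integration over (beta0, a)."""
        rng = np.random.default_rng(2)
        n = 5
        u = rng.normal(size=n)
        z = rng.normal(size=n)
        lam = rng.gamma(3, 0.5, n)
        d = PairedDesign(np.zeros(n, dtype=int), u[:, None], np.zeros((n, 1)))
        prior = PriorSpec(tau_a=1.5, intercept_sd=2.0, kmax=1)
        s_a = 0.8
        got = integrated_log_marginal(ModelConfiguration((), (0,)),
                                      _aug(z, lam), d, prior, s_a, 1.0)
        sig_a2 = prior.tau_a ** 2 / s_a

        def integrand(a, b0):
            resid = z - b0 - a * u
            ll = -0.5 * np.sum(resid ** 2 / lam + np.log(2 * np.pi * lam))
            lp = (-0.5 * (b0 ** 2 / 4.0 + a ** 2 / sig_a2)
                  - 0.5 * math.log(2 * math.pi * 4.0)
                  - 0.5 * math.log(2 * math.pi * sig_a2))
            return math.exp(ll + lp - got)  # scaled to O(1)

        val = dblquad(integrand, -15, 15, -15, 15, epsabs=1e-10)[0]
        assert math.log(val) == pytest.approx(0.0, abs=1e-6)


class TestAcceptanceProbability:
    def _setup(self):
        rng = np.random.default_rng(3)
        n, p = 8, 3
        d = PairedDesign(np.zeros(n, dtype=int), rng.normal(size=(n, p)),
                         rng.normal(size=(n, p)))
        aug = _aug(rng.normal(size=n), rng.gamma(2, 1, n))
        return d, aug, PriorSpec(kmax=3)

    def test_degenerate_proposal_accepted(self):
        d, aug, prior = self._setup()
        cfg = ModelConfiguration((), (0,))
        prop = MoveProposal(BIRTH_SINGLETON, 0, cfg)
        assert acceptance_probability(cfg, prop, aug, d, prior, 1, 1) == 1.0

    def test_inconsistent_proposal_rejected(self):
        d, aug, prior = self._setup()
        cfg = ModelConfiguration((), (0,))
        bad = MoveProposal(BIRTH_SINGLETON, 1, ModelConfiguration((2,), (0,)))
        with pytest.raises(ValueError, match="inconsistent"):
            acceptance_probability(cfg, bad, aug, d, prior, 1, 1)

    def test_in_unit_interval(self):
        d, aug, prior = self._setup()
        rng = np.random.default_rng(4)
        from pairsel import move_probabilities, propose_move
        cfg = ModelConfiguration((), ())
        for _ in range(200):
            probs = move_probabilities(cfg.k_I, cfg.k_C, prior.kmax)
            prop = propose_move(cfg, probs, d.p, rng)
            A = acceptance_probability(cfg, prop, aug, d, prior, 1, 1)
            assert 0.0 <= A <= 1.0
            if rng.random() < A:
                cfg = prop.config


class TestCoefficientUpdate:
    def _system(self, seed=5, n=20):
        rng = np.random.default_rng(seed)
        d = PairedDesign(np.zeros(n, dtype=int), rng.normal(size=(n, 2)),
                         rng.normal(size=(n, 2)))
        aug = _aug(rng.normal(size=n), rng.gamma(2, 1, n))
        return d, aug, PriorSpec(kmax=2)

    def test_degenerate_prior_concentrates_at_zero(self):
        d, aug, _ = self._system()
        prior = PriorSpec(tau_a=1e-6, tau_b=1e-6, intercept_sd=10, kmax=2)
        rng = np.random.default_rng(0)
        cfg = ModelConfiguration((0,), (1,))
        draws = [update_coefficients(cfg, aug, d, prior, 1, 1, rng)
                 for _ in range(50)]
        assert max(np.abs(c.a).max() for c in draws) < 1e-4
        assert max(abs(c.b[0]) for c in draws) < 1e-4

    def test_intercept_only_matches_conjugate_formula(self):
        d, aug, prior = self._system()
        rng = np.random.default_rng(1)
        cfg = ModelConfiguration()
        draws = np.array([
            update_coefficients(cfg, aug, d, prior, 1, 1, rng).beta0
            for _ in range(20_000)])
        w = 1.0 / aug.lam
        post_var = 1.0 / (w.sum() + 1.0 / prior.intercept_sd ** 2)
        post_mean = post_var * (w @ aug.z)
        assert draws.mean() == pytest.approx(post_mean,
                                             abs=4 * math.sqrt(post_var / 20_000))
        assert draws.var() == pytest.approx(post_var, rel=0.05)

    def test_monte_carlo_mean_matches_analytic(self):
        d, aug, prior = self._system(seed=9)
        cfg = ModelConfiguration((1,), (0,))
        sys = _GaussSystem(cfg, _AugCache(aug), d, prior, 1.2, 0.8)
        m, cov = sys.posterior_mean_cov()
        rng = np.random.default_rng(2)
        N = 10_000
        draws = np.array([sys.draw_beta(rng) for _ in range(N)])
        for j in range(m.size):
            assert draws[:, j].mean() == pytest.approx(
                m[j], abs=4 * math.sqrt(cov[j, j] / N))


class TestVarianceScales:
    def test_empty_model_draws_from_prior(self):
        prior = PriorSpec(alpha=2.0, beta=3.0, kmax=2)
        cfg = ModelConfiguration()
        coeffs = CoefficientState(0.0, np.zeros(0), np.zeros(0), 1, 1)
        rng = np.random.default_rng(0)
        draws = np.array([update_variance_scales(coeffs, cfg, prior, rng)[0]
                          for _ in range(5000)])
        p = kstest(draws, gamma_dist(a=2.0, scale=1 / 3.0).cdf).pvalue
        assert p > 1e-3

    def test_single_effect_conjugacy(self):
        """alpha=beta=1 and a^2/(2 tau_a^2) = 1 gives s_a ~ Gamma(1.5, 2)."""
        prior = PriorSpec(alpha=1.0, beta=1.0, tau_a=1.0, kmax=1)
        cfg = ModelConfiguration((), (0,))
        coeffs = CoefficientState(0.0, np.array([math.sqrt(2.0)]),
                                  np.zeros(0), 1, 1)
        rng = np.random.default_rng(1)
        draws = np.array([update_variance_scales(coeffs, cfg, prior, rng)[0]
                          for _ in range(5000)])
        p = kstest(draws, gamma_dist(a=1.5, scale=0.5).cdf).pvalue
        assert p > 1e-3

    def test_posterior_mean_decreases_with_effect_size(self):
        prior = PriorSpec(kmax=1)
        cfg = ModelConfiguration((), (0,))
        means = []
        for a in (0.5, 2.0, 8.0):
            rng = np.random.default_rng(5)
            coeffs = CoefficientState(0.0, np.array([a]), np.zeros(0), 1, 1)
            means.append(np.mean([
                update_variance_scales(coeffs, cfg, prior, rng)[0]
                for _ in range(2000)]))
        assert means[0] > means[1] > means[2]
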