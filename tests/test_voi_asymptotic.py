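import math
import warnings

import numpy as np
import pytest

from voival import (
    DegenerateSampleWarning,
    SimConfig,
    ValidationSample,
    emax0_bvn,
    emax0_bvn_closed,
    evpi_asymptotic,
    evpi_bootstrap,
    generate_sample,
    nb_moments,
    p_model_best,
    posterior_draws,
)

# mean of max(0, Z1, Z2) for independent standard normals: the max of two has
# mean 1/sqrt(pi); adding the 0 floor contributes the unit normal loss at the
# origin of the max's distribution, giving 1/sqrt(2 pi) + 1/(2 sqrt(pi))
EMAX0_STD_INDEP = 1 / math.sqrt(2 * math.pi) + 1 / (2 * math.sqrt(math.pi))


def random_psd(rng, scale=1.0):
    A = rng.normal(size=(2, 2)) * scale
    return A @ A.T


class TestNbMoments:
    def test_toy_hand_arithmetic(self, toy_sample):
        m = nb_moments(toy_sample, 0.5)
        assert m.p_tp == m.p_fp == 0.25
        assert m.p0 == 0.5
        assert m.sigma[0, 0] == pytest.approx(0.125)
        assert m.sigma[1, 1] == pytest.approx(0.25)
        assert m.sigma[0, 1] == pytest.approx(0.125)
        assert m.mu[0] == pytest.approx(0.0)
        assert m.mu[1] == pytest.approx(0.0)

    def test_no_events_collapses(self):
        s = ValidationSample(y=[0, 0, 0], pi=[0.9, 0.2, 0.4])
        m = nb_moments(s, 0.5)
        assert m.sigma[1, 1] == 0.0
        assert m.sigma[0, 1] == 0.0

    def test_threshold_zero_limits(self, toy_sample):
        m = nb_moments(toy_sample, 0.0)
        p0 = toy_sample.prevalence
        n = toy_sample.n
        assert m.p_tp == p0
        assert m.sigma[0, 0] == pytest.approx(p0 * (1 - p0) / n)
        assert m.sigma[1, 1] == pytest.approx(p0 * (1 - p0) / n)
        assert m.sigma[0, 1] == pytest.approx(p0 * (1 - p0) / n)

    @pytest.mark.parametrize("n,z", [(250, 0.1), (250, 0.2), (1000, 0.1), (1000, 0.2)])
    def test_formula_matches_bootstrap_covariance(self, n, z):
        """The closed-form covariance of the two NB estimators matches the
        empirical covariance of ordinary-bootstrap draws within 3 MC SEs."""
        s = generate_sample(SimConfig(n=n, seed=5))
        m = nb_moments(s, z)
        B = 10_000
        d = posterior_draws(s, z, B=B, scheme="ordinary", seed=2)
        emp = np.cov(np.vstack([d.nb_model, d.nb_all]), ddof=1)
        se = np.array([
            [m.sigma[0, 0] * math.sqrt(2 / B),
             math.sqrt((m.sigma[0, 0] * m.sigma[1, 1] + m.sigma[0, 1] ** 2) / B)],
            [0.0, m.sigma[1, 1] * math.sqrt(2 / B)]])
        assert abs(emp[0, 0] - m.sigma[0, 0]) < 3 * se[0, 0]
        assert abs(emp[1, 1] - m.sigma[1, 1]) < 3 * se[1, 1]
        assert abs(emp[0, 1] - m.sigma[0, 1]) < 3 * se[0, 1]


class TestEmax0:
    def test_point_mass(self):
        assert emax0_bvn([0.3, -0.1], np.zeros((2, 2))) == pytest.approx(0.3)
        assert emax0_bvn([-0.3, -0.1], np.zeros((2, 2))) == 0.0

    def test_mass_entirely_below_zero(self):
        assert emax0_bvn([-10, -10], np.eye(2) * 1e-4) == pytest.approx(0.0, abs=1e-12)

    def test_independent_standard_normals_analytic(self):
        assert emax0_bvn([0, 0], np.eye(2)) == pytest.approx(EMAX0_STD_INDEP, abs=1e-9)
        assert emax0_bvn_closed([0, 0], np.eye(2)) == pytest.approx(EMAX0_STD_INDEP, abs=1e-12)

    def test_closed_form_matches_quadrature(self, rng):
        """Reference quadrature and the closed form agree to 1e-9 across
        random means and covariances on the NB scale."""
        for _ in range(25):
            mu = rng.normal(scale=0.05, size=2)
            sigma = random_psd(rng, scale=0.02)
            q = emax0_bvn(mu, sigma)
            c = emax0_bvn_closed(mu, sigma)
            assert abs(q - c) < 1e-9, (mu, sigma)

    def test_monte_carlo_oracle(self, rng):
        """1e7-draw Monte Carlo cross-check of the loss integral (3 MC SEs)."""
        mu = np.array([0.02, 0.015])
        sigma = np.array([[4e-4, 1.5e-4], [1.5e-4, 2.5e-4]])
        draws = rng.multivariate_normal(mu, sigma, size=10_000_000)
        vals = np.maximum(0.0, draws.max(axis=1))
        mc = vals.mean()
        se = vals.std() / math.sqrt(vals.size)
        assert abs(emax0_bvn(mu, sigma) - mc) < 3 * se
        assert abs(emax0_bvn_closed(mu, sigma) - mc) < 3 * se

    def test_jensen_lower_bound(self, rng):
        for _ in range(20):
            mu = rng.normal(size=2)
            sigma = random_psd(rng)
            assert emax0_bvn_closed(mu, sigma) >= max(0.0, mu[0], mu[1]) - 1e-12

    def test_symmetry_under_component_swap(self, rng):
        for _ in range(10):
            mu = rng.normal(size=2)
            sigma = random_psd(rng)
            swapped = sigma[::-1, ::-1]
            assert emax0_bvn(mu, sigma) == pytest.approx(
                emax0_bvn(mu[::-1], swapped), abs=1e-10)
            assert emax0_bvn_closed(mu, sigma) == pytest.approx(
                emax0_bvn_closed(mu[::-1], swapped), abs=1e-12)

    def test_monotone_in_marginal_variance(self):
        mu = [0.1, 0.1]
        vals = [emax0_bvn(mu, np.diag([v, 0.5])) for v in (0.1, 0.5, 1.0, 2.0)]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_perfect_correlation_limit(self):
        """Rank-1 covariance (both components a linear function of one normal)
        is handled analytically: N1 = N2 reduces to the univariate loss."""
        sigma = np.array([[1.0, 1.0], [1.0, 1.0]])
        got = emax0_bvn([0.0, 0.0], sigma)
        # max(0, N, N) = max(0, N), mean phi(0)
        assert got == pytest.approx(1 / math.sqrt(2 * math.pi), abs=1e-9)
        assert emax0_bvn_closed([0.0, 0.0], sigma) == pytest.approx(got, abs=1e-9)

    def test_non_psd_rejected(self):
        with pytest.raises(ValueError):
            emax0_bvn([0, 0], np.array([[1.0, 2.0], [2.0, 1.0]]))


class TestPModelBest:
    def test_independent_symmetric(self):
        # P(Z1 > 0, Z1 > Z2) for iid standard normals = 3/8
        assert p_model_best([0, 0], np.eye(2)) == pytest.approx(3 / 8, abs=1e-9)

    def test_point_masses(self):
        assert p_model_best([0.2, 0.1], np.zeros((2, 2))) == 1.0
        assert p_model_best([0.1, 0.1], np.zeros((2, 2))) == 0.0  # tie: against model

    def test_monte_carlo_oracle(self, rng):
        mu = np.array([0.01, 0.012])
        sigma = np.array([[4e-4, 1e-4], [1e-4, 3e-4]])
        draws = rng.multivariate_normal(mu, sigma, size=2_000_000)
        mc = np.mean(draws[:, 0] > np.maximum(0.0, draws[:, 1]))
        se = math.sqrt(mc * (1 - mc) / draws.shape[0])
        assert abs(p_model_best(mu, sigma) - mc) < 3 * se


class TestEvpiAsymptotic:
    def test_zero_variance_sample(self):
        s = ValidationSample(y=[1, 1, 1], pi=[0.9, 0.8, 0.7])
        with pytest.warns(DegenerateSampleWarning):
            r = evpi_asymptotic(s, 0.5)
        assert r.evpi == 0.0

    def test_agrees_with_bootstrap(self):
        """Asymptotic EVPI tracks the B=1e4 bootstrap EVPI on n=500
        correct-model samples (20% relative or 1e-4 absolute)."""
        for seed in (3, 5, 9):
            s = generate_sample(SimConfig(n=500, seed=seed))
            ra = evpi_asymptotic(s, 0.2)
            rb = evpi_bootstrap(s, 0.2, B=10_000, scheme="bayesian", seed=7)
            assert abs(ra.evpi - rb.evpi) <= max(0.2 * rb.evpi, 1e-4)

    def test_large_sample_evpi_vanishes(self):
        """With a 23,034-subject validation sample the EVPI is numerically
        zero at a threshold where the model clearly beats the defaults
        (z = 0.2, where the true incremental NB is large)."""
        s = generate_sample(SimConfig(n=23_034, seed=1))
        r = evpi_asymptotic(s, 0.2)
        assert r.evpi < 1e-6

    def test_large_sample_near_tied_strategies_keep_value(self):
        """At a threshold far below prevalence the model and treat-all nearly
        coincide, so even a very large sample leaves real decision
        uncertainty and a positive EVPI."""
        s = generate_sample(SimConfig(n=23_034, seed=1))
        r = evpi_asymptotic(s, 0.05)
        assert r.evpi > 1e-6

    def test_result_metadata(self, sim_sample_500):
        r = evpi_asymptotic(sim_sample_500, 0.2)
        assert r.method == "asymptotic"
        assert r.B is None
        assert 0.0 <= r.p_useful <= 1.0
        assert r.evpi >= 0.0
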