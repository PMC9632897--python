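import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, optimize, stats

from oracles import (direct_cdf_quantile, direct_cdf_shape, fd_grad, fd_hess)
from ubxii import distribution as dist
from ubxii.distribution import QuantileParams, ShapeParams

TABLE1 = [(1.5, 0.3), (0.9, 0.7), (1.1, 0.4), (2.0, 0.4), (1.7, 0.6), (3.5, 0.5)]


class TestShapeParameterization:
    def test_cdf_closed_form(self):
        # c=d=1 at y=e^{-1}: (1 + 1)^{-1}
        assert dist.cdf_shape(math.exp(-1), ShapeParams(1, 1)) == pytest.approx(0.5)

    def test_cdf_direct_arithmetic(self):
        assert dist.cdf_shape(0.5, ShapeParams(1.5, 3.4)) == pytest.approx(
            0.2124685430933631, abs=1e-12
        )
        assert dist.cdf_shape(0.5, ShapeParams(1.5, 3.4)) == pytest.approx(
            direct_cdf_shape(0.5, 1.5, 3.4), abs=1e-14
        )

    def test_pdf_closed_form(self):
        assert dist.pdf_shape(math.exp(-1), ShapeParams(1, 1)) == pytest.approx(
            math.e / 4
        )

    def test_pdf_is_cdf_derivative(self):
        p = ShapeParams(2.0, 1.7)
        h = 1e-6
        fd = (dist.cdf_shape(0.3 + h, p) - dist.cdf_shape(0.3 - h, p)) / (2 * h)
        assert dist.pdf_shape(0.3, p) == pytest.approx(fd, rel=1e-6)

    def test_pdf_integrates_to_one(self):
        p = ShapeParams(1.5, 3.4)
        val, _ = integrate.quad(lambda y: float(dist.pdf_shape(y, p)), 0, 1,
                                limit=200)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_qf_closed_form(self):
        assert dist.qf_shape(0.5, ShapeParams(1, 1)) == pytest.approx(math.exp(-1))

    def test_qf_matches_bisection(self):
        # independent root of cdf(y) = 0.25
        assert dist.qf_shape(0.25, ShapeParams(1.5, 3.4)) == pytest.approx(
            0.5310927006906017, abs=1e-9
        )

    @pytest.mark.parametrize("u", [0.01, 0.5, 0.99])
    def test_cdf_qf_inverse(self, u):
        p = ShapeParams(3.5, 0.8)
        assert dist.cdf_shape(dist.qf_shape(u, p), p) == pytest.approx(u, abs=1e-10)

    @pytest.mark.parametrize("y", [0.0, 1.0, -0.2, 1.5])
    def test_domain_errors(self, y):
        with pytest.raises(ValueError):
            dist.cdf_shape(y, ShapeParams(1, 1))


class TestQuantileParameterization:
    def test_d_from_quantile_closed_form(self):
        # c=1, q=e^{-1}, tau=0.5: log 2 / log 2
        assert dist.d_from_quantile(
            QuantileParams(1.0, math.exp(-1), 0.5)
        ) == pytest.approx(1.0)

    def test_d_roundtrip_through_shape_qf(self):
        p = QuantileParams(2.3, 0.7, 0.5)
        assert dist.qf_shape(p.tau, p.to_shape()) == pytest.approx(p.q, abs=1e-12)

    def test_d_matches_numeric_solve(self):
        # root of qf_shape(tau; c, d) = q in d
        d = optimize.brentq(
            lambda dd: dist.qf_shape(0.5, ShapeParams(1.5, dd)) - 0.3, 1e-6, 1e3,
            xtol=1e-13,
        )
        assert dist.d_from_quantile(QuantileParams(1.5, 0.3, 0.5)) == pytest.approx(
            d, abs=1e-9
        )

    @pytest.mark.parametrize("c,q", TABLE1)
    def test_cdf_at_q_is_tau(self, c, q):
        for tau in (0.1, 0.5, 0.9):
            assert dist.cdf(q, QuantileParams(c, q, tau)) == pytest.approx(
                tau, abs=1e-14
            )

    def test_cdf_equals_shape_cdf_on_grid(self):
        p = QuantileParams(2.0, 0.4, 0.5)
        sp = p.to_shape()
        y = np.linspace(0.05, 0.95, 10)
        np.testing.assert_allclose(dist.cdf(y, p), dist.cdf_shape(y, sp),
                                   atol=1e-12)

    def test_cdf_direct_arithmetic(self):
        assert dist.cdf(0.8, QuantileParams(1.1, 0.4, 0.5)) == pytest.approx(
            0.8282479348962596, abs=1e-12
        )
        assert dist.cdf(0.8, QuantileParams(1.1, 0.4, 0.5)) == pytest.approx(
            direct_cdf_quantile(0.8, 1.1, 0.4, 0.5), abs=1e-14
        )

    @pytest.mark.parametrize("c,q", TABLE1)
    def test_pdf_integrates_to_one(self, c, q):
        # The lower tail is polynomially heavy in w = -log y (mass of order
        # 1e-4 lies below the smallest positive double), so integrate in the
        # w domain with an independently coded direct-arithmetic integrand.
        tau = 0.5
        lam = -math.log(tau)
        L = math.log(1.0 + (-math.log(q)) ** c)

        def w_density(w):
            return (c * lam / L) * w ** (c - 1.0) \
                * (1.0 + w**c) ** (math.log(tau) / L - 1.0)

        # the library pdf agrees with the substituted integrand...
        p = QuantileParams(c, q, tau)
        for w in (0.3, 1.0, 2.5):
            y = math.exp(-w)
            assert float(dist.pdf(y, p)) * y == pytest.approx(
                w_density(w), rel=1e-10
            )
        # ...which integrates to one
        val, _ = integrate.quad(w_density, 0, np.inf, limit=400)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_pdf_equals_shape_pdf_on_grid(self):
        p = QuantileParams(2.0, 0.4, 0.5)
        sp = p.to_shape()
        y = np.linspace(0.05, 0.95, 10)
        np.testing.assert_allclose(dist.pdf(y, p), dist.pdf_shape(y, sp),
                                   rtol=1e-12)

    def test_qf_at_tau_is_q(self):
        for c, q in TABLE1:
            assert dist.qf(0.5, QuantileParams(c, q, 0.5)) == pytest.approx(
                q, abs=1e-14
            )

    def test_qf_matches_bisection(self):
        assert dist.qf(0.25, QuantileParams(1.7, 0.6, 0.5)) == pytest.approx(
            0.4326302857822399, abs=1e-9
        )

    @pytest.mark.parametrize("c,q", TABLE1)
    def test_cdf_qf_identity_grid(self, c, q):
        p = QuantileParams(c, q, 0.5)
        u = np.arange(0.1, 0.95, 0.1)
        np.testing.assert_allclose(dist.cdf(dist.qf(u, p), p), u, atol=1e-10)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        c=st.floats(0.2, 8.0),
        q=st.floats(0.05, 0.95),
        tau=st.floats(0.1, 0.9),
        u=st.floats(0.01, 0.99),
    )
    def test_roundtrip_property(self, c, q, tau, u):
        from hypothesis import assume

        p = QuantileParams(c, q, tau)
        y = float(dist.qf(u, p))
        # extreme tails can leave the representable interior of (0, 1)
        assume(0.0 < y < 1.0)
        assert dist.cdf(y, p) == pytest.approx(u, abs=1e-9)


class TestSamplingAndShape:
    def test_sample_deterministic(self):
        p = QuantileParams(2.0, 0.4, 0.5)
        np.testing.assert_array_equal(dist.sample(100, p, seed=5),
                                      dist.sample(100, p, seed=5))

    def test_sample_median_proportion(self):
        p = QuantileParams(2.0, 0.4, 0.5)
        y = dist.sample(50_000, p, seed=11)
        prop = np.mean(y <= 0.4)
        assert abs(prop - 0.5) < 3 * math.sqrt(0.25 / 50_000)

    def test_sample_ks_calibration(self):
        # KS distance below the 1% critical value in >= 95% of repetitions
        p = QuantileParams(2.0, 0.4, 0.5)
        n, reps = 20_000, 60
        crit = 1.628 / math.sqrt(n)   # asymptotic 1% point
        ok = 0
        for r in range(reps):
            y = dist.sample(n, p, seed=(123, r))
            d = stats.kstest(y, lambda v: dist.cdf(v, p)).statistic
            ok += d < crit
        assert ok / reps >= 0.95

    def test_sample_rejects_bad_n(self):
        with pytest.raises(ValueError):
            dist.sample(0, QuantileParams(1, 0.5, 0.5))

    def test_shape_measures_bounds(self):
        cs = np.linspace(0.3, 6.0, 20)
        qs = np.linspace(0.05, 0.95, 20)
        for c in cs:
            for q in qs:
                b, m = dist.shape_measures(QuantileParams(c, q, 0.5))
                assert -1.0 <= b <= 1.0
                assert m > 0.0

    def test_bowley_two_path(self):
        p = QuantileParams(1.7, 0.6, 0.5)
        b, _ = dist.shape_measures(p)
        Q = lambda u: float(dist.qf(u, p))
        direct = (Q(0.75) - 2 * Q(0.5) + Q(0.25)) / (Q(0.75) - Q(0.25))
        assert b == pytest.approx(direct, abs=1e-12)


class TestLikelihood:
    def test_single_observation(self):
        p = QuantileParams(1.5, 0.3, 0.5)
        assert dist.loglik([0.42], p) == pytest.approx(
            float(dist.logpdf(0.42, p))
        )

    def test_permutation_invariance(self, scenario1_sample):
        p = QuantileParams(1.5, 0.3, 0.5)
        rng = np.random.default_rng(3)
        shuffled = rng.permutation(scenario1_sample)
        assert dist.loglik(shuffled, p) == pytest.approx(
            dist.loglik(scenario1_sample, p), abs=1e-9
        )

    def test_two_path_sum_of_logpdf(self, scenario1_sample):
        p = QuantileParams(1.3, 0.35, 0.5)
        assert dist.loglik(scenario1_sample, p) == pytest.approx(
            float(np.sum(dist.logpdf(scenario1_sample, p))), abs=1e-9
        )

    def test_rejects_boundary_observation(self):
        with pytest.raises(ValueError, match="1"):
            dist.loglik([0.2, 1.0, 0.4], QuantileParams(1, 0.5, 0.5))

    def test_score_matches_finite_differences(self, scenario1_sample):
        y = scenario1_sample
        theta = np.array([1.5, 0.3])
        f = lambda th: dist.loglik(y, QuantileParams(th[0], th[1], 0.5))
        np.testing.assert_allclose(
            dist.score(y, QuantileParams(1.5, 0.3, 0.5)), fd_grad(f, theta),
            rtol=1e-6,
        )

    def test_score_additivity(self, scenario1_sample):
        p = QuantileParams(1.5, 0.3, 0.5)
        doubled = np.concatenate([scenario1_sample, scenario1_sample])
        np.testing.assert_allclose(
            dist.score(doubled, p), 2 * dist.score(scenario1_sample, p),
            rtol=1e-12,
        )

    def test_observed_info_matches_numeric_hessian(self):
        y = dist.sample(300, QuantileParams(2.0, 0.4, 0.5), seed=44)
        theta = np.array([2.0, 0.4])
        f = lambda th: dist.loglik(y, QuantileParams(th[0], th[1], 0.5))
        J = dist.observed_info(y, QuantileParams(2.0, 0.4, 0.5))
        np.testing.assert_allclose(J, -fd_hess(f, theta), rtol=1e-4)
        assert J[0, 1] == J[1, 0]

    def test_observed_info_positive_definite_at_mle(self, scenario1_sample):
        f = dist.fit(scenario1_sample, 0.5)
        assert np.all(np.linalg.eigvalsh(f.observed_info) > 0)


class TestProfile:
    def test_qhat_zeroes_score(self):
        y = dist.sample(150, QuantileParams(0.9, 0.7, 0.5), seed=7)
        for c in (0.7, 1.2, 2.5):
            qh = dist.qhat_given_c(y, c, 0.5)
            assert dist.score(y, QuantileParams(c, qh, 0.5))[1] == pytest.approx(
                0.0, abs=1e-8
            )

    def test_qhat_single_observation_matches_1d_maximizer(self):
        # for n=1 the conditional MLE of q still comes from the stationarity
        # equation log t(q) = log(1/tau) * log t(y); check it against a
        # direct 1-D maximization of the log-likelihood in q
        y = [0.37]
        for c, tau in [(0.2, 0.5), (1.3, 0.5), (5.0, 0.3)]:
            res = optimize.minimize_scalar(
                lambda q: -dist.loglik(y, QuantileParams(c, q, tau)),
                bounds=(1e-9, 1 - 1e-9), method="bounded",
                options={"xatol": 1e-12},
            )
            assert dist.qhat_given_c(y, c, tau) == pytest.approx(res.x, abs=1e-7)
        # the stationary point coincides with the observation when tau = 1/e
        assert dist.qhat_given_c(y, 1.3, math.exp(-1)) == pytest.approx(0.37)

    def test_qhat_stays_interior(self, scenario1_sample):
        for c in (0.2, 1.0, 5.0):
            assert 0.0 < dist.qhat_given_c(scenario1_sample, c, 0.5) < 1.0

    def test_profile_equals_substituted_loglik(self, scenario1_sample):
        y = scenario1_sample
        for c in (0.5, 1.5, 3.0):
            qh = dist.qhat_given_c(y, c, 0.5)
            assert dist.profile_loglik(y, c, 0.5) == pytest.approx(
                dist.loglik(y, QuantileParams(c, qh, 0.5)), abs=1e-9
            )

    def test_profile_score_matches_finite_difference(self, scenario1_sample):
        y, c = scenario1_sample, 1.8
        h = 1e-6
        fd = (dist.profile_loglik(y, c + h) - dist.profile_loglik(y, c - h)) / (2 * h)
        assert dist.profile_score(y, c) == pytest.approx(fd, rel=1e-6)

    def test_profile_unimodal_single_sign_change(self):
        # mirrors the c=1.5, d=3.4, n=100 unimodality illustration
        d_true = 3.4
        p = ShapeParams(1.5, d_true)
        rng = np.random.default_rng(99)
        y = dist.qf_shape(rng.uniform(size=100), p)
        grid = np.linspace(0.2, 9.0, 150)
        signs = np.sign([dist.profile_score(y, c) for c in grid])
        assert np.sum(np.abs(np.diff(signs)) > 0) == 1

    def test_grid_argmax_matches_fit(self, scenario1_sample):
        f = dist.fit(scenario1_sample, 0.5)
        grid = np.linspace(0.5, 4.0, 400)
        vals = [dist.profile_loglik(scenario1_sample, c) for c in grid]
        assert abs(grid[int(np.argmax(vals))] - f.params.c) < (grid[1] - grid[0]) * 1.5


class TestFit:
    def test_parameter_recovery_large_sample(self):
        p = QuantileParams(3.5, 0.5, 0.5)
        y = dist.sample(10_000, p, seed=2024)
        f = dist.fit(y, 0.5)
        assert f.converged
        assert abs(f.params.c - 3.5) < 3 * f.std_errors[0]
        assert abs(f.params.q - 0.5) < 3 * f.std_errors[1]

    def test_profile_fit_agrees_with_joint_optimizer(self, scenario1_sample):
        y = scenario1_sample
        f = dist.fit(y, 0.5)

        def neg(x):
            c = math.exp(x[0])
            q = 1.0 / (1.0 + math.exp(-x[1]))
            return -dist.loglik(y, QuantileParams(c, q, 0.5))

        res = optimize.minimize(neg, [0.0, 0.0], method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12,
                                         "maxiter": 4000})
        c_j = math.exp(res.x[0])
        q_j = 1.0 / (1.0 + math.exp(-res.x[1]))
        assert f.params.c == pytest.approx(c_j, abs=1e-5)
        assert f.params.q == pytest.approx(q_j, abs=1e-5)

    def test_std_errors_from_inverse_information(self, scenario1_sample):
        f = dist.fit(scenario1_sample, 0.5)
        cov = np.linalg.inv(f.observed_info)
        np.testing.assert_allclose(f.std_errors, np.sqrt(np.diag(cov)),
                                   rtol=1e-10)

    def test_score_small_at_optimum(self, scenario1_sample):
        f = dist.fit(scenario1_sample, 0.5)
        assert np.max(np.abs(dist.score(scenario1_sample, f.params))) < 1e-4

    def test_needs_three_observations(self):
        with pytest.raises(ValueError):
            dist.fit([0.3, 0.5], 0.5)
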