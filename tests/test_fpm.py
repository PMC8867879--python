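"""Relative-survival FPM: fitting, prediction, LLE/PLL, standardisation."""

import numpy as np
import pytest
from scipy import integrate, optimize

from leadtime.fpm import (
    FPMFit,
    ICSSWeights,
    compute_lle,
    compute_pll,
    fit_covariance,
    fit_relative_survival_fpm,
    predict_R,
    standardize,
)
from leadtime.lifetables import expected_survival

from conftest import constant_rate_table


def simulate_weibull_net(n, g0, g1, alpha, rng, censor=12.0, age_lo=40.0, age_hi=80.0):
    """Draws from the Weibull net-survival model with no background mortality."""
    age = rng.uniform(age_lo, age_hi, n)
    e = rng.exponential(size=n)
    t = np.exp((np.log(e) - g0 - alpha * age) / g1)
    fu = np.minimum(t, censor)
    event = t < censor
    return fu, event, age


TRUTH = dict(g0=-2.2, g1=0.8, alpha=0.015)


@pytest.fixture(scope="module")
def weibull_fit():
    rng = np.random.default_rng(2024)
    fu, event, age = simulate_weibull_net(5000, rng=rng, **TRUTH)
    fit = fit_relative_survival_fpm(
        fu, event, age, np.zeros(5000), df_baseline=1, df_tvc=0
    )
    return fit, (fu, event, age)


class TestFitting:
    def test_weibull_parameter_recovery_within_three_se(self, weibull_fit):
        fit, _ = weibull_fit
        cov = fit_covariance(fit)
        se = np.sqrt(np.diag(cov))
        est = np.array([fit.gamma[0], fit.gamma[1], fit.alpha])
        truth = np.array([TRUTH["g0"], TRUTH["g1"], TRUTH["alpha"]])
        assert np.all(np.abs(est - truth) < 3 * se)

    def test_zero_expected_rates_reduce_to_all_cause_likelihood(self, weibull_fit):
        """With h* = 0 the likelihood is the plain parametric all-cause
        likelihood sum(d ln lambda - Lambda); recompute it independently at
        the fitted parameters."""
        fit, (fu, event, age) = weibull_fit
        t = np.maximum(fu, 1 / 365.25)
        g0, g1, a = fit.gamma[0], fit.gamma[1], fit.alpha
        lam_cum = np.exp(g0 + g1 * np.log(t) + a * age)
        lam = lam_cum * g1 / t
        ll = np.sum(event * np.log(lam) - lam_cum)
        assert fit.loglik == pytest.approx(ll, abs=1e-6)

    def test_higher_expected_rates_lower_the_fitted_excess_hazard(self):
        """Holding the all-cause data fixed, attributing more mortality to
        the background must strictly reduce the fitted excess hazard."""
        rng = np.random.default_rng(7)
        fu, event, age = simulate_weibull_net(5000, -1.8, 0.9, 0.0, rng)
        hstar = np.full(5000, 0.02)
        fit1 = fit_relative_survival_fpm(fu, event, age, hstar, df_baseline=1, df_tvc=0)
        fit2 = fit_relative_survival_fpm(fu, event, age, 2 * hstar, df_baseline=1, df_tvc=0)
        for t in (2.0, 5.0, 10.0):
            assert fit2.cumulative_excess_hazard(t, 60.0) < fit1.cumulative_excess_hazard(t, 60.0)

    def test_maximum_matches_brute_force_oracle_on_small_fixture(self):
        """On a 20-record fixture the fitted maximum log-likelihood must
        match an independently coded likelihood maximised by Nelder–Mead
        from several starts."""
        rng = np.random.default_rng(5)
        fu, event, age = simulate_weibull_net(20, -1.5, 1.1, 0.0, rng)
        hstar = np.full(20, 0.01)
        fit = fit_relative_survival_fpm(fu, event, age, hstar, df_baseline=1, df_tvc=0)

        t = np.maximum(fu, 1 / 365.25)

        def negll(p):
            g0, g1, a = p
            if g1 <= 0:
                return 1e10
            lam_cum = np.exp(g0 + g1 * np.log(t) + a * age)
            lam = lam_cum * g1 / t
            with np.errstate(invalid="ignore"):
                val = np.sum(event * np.log(hstar + lam) - lam_cum)
            return 1e10 if not np.isfinite(val) else -val

        best = np.inf
        for start in ([-1, 1, 0], [-2, 0.5, 0.01], [0.5, 2, -0.01]):
            r = optimize.minimize(negll, start, method="Nelder-Mead",
                                  options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
            best = min(best, r.fun)
        assert fit.loglik == pytest.approx(-best, abs=1e-4)

    def test_too_few_events_raise(self):
        with pytest.raises(ValueError):
            fit_relative_survival_fpm([1.0, 2.0], [True, False], [60, 61], [0, 0])

    def test_df3_with_tvc_fits_and_serialises(self, tmp_path):
        rng = np.random.default_rng(33)
        fu, event, age = simulate_weibull_net(2000, -2.0, 0.9, 0.01, rng)
        fit = fit_relative_survival_fpm(fu, event, age, np.zeros(2000))
        assert fit.converged and fit.delta is not None and fit.delta.size == 3
        path = tmp_path / "fit.json"
        fit.to_text(path)
        clone = FPMFit.from_text(path)
        ts = np.array([0.5, 2.0, 9.0])
        np.testing.assert_allclose(
            predict_R(clone, 60.0, ts), predict_R(fit, 60.0, ts), rtol=0, atol=1e-12
        )


class TestPrediction:
    def weibull_fit_object(self, g0=-2.0, g1=0.9, alpha=0.01):
        return FPMFit(knots=np.log([0.1, 12.0]), gamma=[g0, g1], alpha=alpha)

    def test_limit_at_time_zero_is_one(self):
        fit = self.weibull_fit_object()
        assert predict_R(fit, 60.0, 0.0) == 1.0
        assert predict_R(fit, 60.0, 1e-12) == pytest.approx(1.0, abs=1e-6)

    def test_monotone_non_increasing(self):
        fit = self.weibull_fit_object()
        ts = np.linspace(0.01, 40, 500)
        r = predict_R(fit, 55.0, ts)
        assert np.all(np.diff(r) <= 1e-15)

    def test_weibull_closed_form_to_1e8(self):
        g0, g1, a = -2.0, 0.9, 0.01
        fit = self.weibull_fit_object(g0, g1, a)
        for t in (0.5, 1.0, 5.0, 10.0):
            closed = np.exp(-np.exp(g0 + g1 * np.log(t) + a * 62.0))
            assert predict_R(fit, 62.0, t) == pytest.approx(closed, abs=1e-8)


class TestLifeExpectancyMeasures:
    def flat_fit(self, excess):
        """Constant-excess-hazard model: Lambda(t) = excess * t."""
        return FPMFit(knots=np.log([0.1, 12.0]), gamma=[np.log(excess), 1.0], alpha=0.0)

    def test_no_excess_hazard_means_no_loss(self):
        table = constant_rate_table(0.05)
        fit = FPMFit(knots=np.log([0.1, 12.0]), gamma=[-100.0, 1.0], alpha=0.0)
        lle = compute_lle(fit, table, 40.0, 1972.0, t_max=50.0)
        assert abs(lle) < 1e-8

    def test_constant_rates_truncated_closed_form(self):
        """Expected rate 0.05 and excess rate 0.05: LLE_T =
        (1-e^{-0.05T})/0.05 - (1-e^{-0.1T})/0.1 exactly."""
        table = constant_rate_table(0.05, years=(1870, 2400), age_cap=300)
        fit = self.flat_fit(0.05)
        for T in (20.0, 60.0):
            closed = (1 - np.exp(-0.05 * T)) / 0.05 - (1 - np.exp(-0.1 * T)) / 0.1
            lle = compute_lle(fit, table, 40.0, 1972.0, t_max=T)
            assert lle == pytest.approx(closed, abs=1e-6)

    def test_constant_rates_limits(self):
        """As t_max grows the loss tends to 1/0.05 - 1/0.1 = 10 years and
        the proportion of life lost to 1/2."""
        table = constant_rate_table(0.05, years=(1870, 2400), age_cap=300)
        fit = self.flat_fit(0.05)
        lle = compute_lle(fit, table, 40.0, 1972.0, t_max=250.0)
        pll = compute_pll(lle, table, 40.0, 1972.0, t_max=250.0)
        assert lle == pytest.approx(10.0, abs=1e-3)
        assert pll == pytest.approx(0.5, abs=1e-4)

    def test_quadrature_node_doubling_converged(self):
        table = constant_rate_table(0.03)
        fit = self.flat_fit(0.08)
        a = compute_lle(fit, table, 55.0, 1971.0, nodes=8)
        b = compute_lle(fit, table, 55.0, 1971.0, nodes=16)
        assert abs(a - b) < 1e-6

    def test_agrees_with_adaptive_quadrature_oracle(self):
        """Independent oracle: scipy adaptive quadrature of S*(t)(1 - R(t))
        on a fitted df-3 model."""
        rng = np.random.default_rng(8)
        fu, event, age = simulate_weibull_net(2000, -2.0, 0.9, 0.01, rng)
        fit = fit_relative_survival_fpm(fu, event, age, np.zeros(2000))
        table = constant_rate_table(0.04)
        age_dx, year_dx = 57.3, 1972.4
        t_max = 100.0 - age_dx
        lle = compute_lle(fit, table, age_dx, year_dx, t_max)

        def integrand(u):
            s = expected_survival(table, age_dx, year_dx, u)
            return s * (1.0 - predict_R(fit, age_dx, u))

        pieces = np.linspace(0.0, t_max, 200)
        oracle = sum(
            integrate.quad(integrand, lo, hi, epsabs=1e-10, limit=200)[0]
            for lo, hi in zip(pieces[:-1], pieces[1:])
        )
        assert lle == pytest.approx(oracle, abs=1e-5)

    def test_lle_nonnegative_and_decreasing_in_survival(self):
        table = constant_rate_table(0.05)
        low = self.flat_fit(0.08)
        high = self.flat_fit(0.02)  # better net survival
        a = compute_lle(low, table, 50.0, 1972.0)
        b = compute_lle(high, table, 50.0, 1972.0)
        assert a > b >= 0.0

    def test_pll_bounds_and_trivial_zero(self):
        table = constant_rate_table(0.05)
        assert compute_pll(0.0, table, 50.0, 1972.0) == 0.0
        fit = self.flat_fit(0.1)
        lle = compute_lle(fit, table, 50.0, 1972.0)
        pll = compute_pll(lle, table, 50.0, 1972.0)
        assert 0.0 <= pll <= 1.0

    def test_invalid_t_max_raises(self):
        table = constant_rate_table(0.05)
        with pytest.raises(ValueError):
            compute_lle(self.flat_fit(0.05), table, 50.0, 1972.0, t_max=0.0)


class TestStandardisation:
    def test_sample_matching_reference_gives_unit_weights(self, rng):
        w = ICSSWeights()
        ages = np.concatenate([
            np.full(7, 40.0), np.full(12, 50.0), np.full(23, 60.0),
            np.full(29, 70.0), np.full(29, 80.0),
        ])
        values = rng.uniform(0, 1, ages.size)
        np.testing.assert_allclose(w.individual_weights(ages), 1.0)
        assert standardize(values, ages, w) == pytest.approx(values.mean())

    def test_two_group_toy_hand_arithmetic(self):
        w = ICSSWeights(
            groups=((-np.inf, 45.0), (45.0, 55.0)),
            proportions=(0.07 / 0.19, 0.12 / 0.19),
        )
        ages = np.array([40.0, 40.0, 50.0, 50.0])
        values = np.array([0.4, 0.4, 0.8, 0.8])
        expected = (0.07 * 0.4 + 0.12 * 0.8) / 0.19
        assert standardize(values, ages, w) == pytest.approx(expected)

    def test_constant_values_invariant_under_weights(self, rng):
        ages = rng.uniform(30, 90, 200)
        assert standardize(np.full(200, 0.37), ages, ICSSWeights()) == pytest.approx(0.37)

    def test_plain_mean_without_weights(self):
        assert standardize([0.2, 0.4, 0.9]) == pytest.approx(0.5)

    def test_empty_reference_group_raises(self):
        ages = np.full(50, 60.0)  # only one ICSS group populated
        with pytest.raises(ValueError, match="empty"):
            standardize(np.ones(50), ages, ICSSWeights())

    def test_empty_cohort_raises(self):
        with pytest.raises(ValueError):
            standardize([])

    def test_mean_weight_is_one_when_all_groups_present(self, rng):
        ages = rng.uniform(30.0, 95.0, 500)
        w = ICSSWeights().individual_weights(ages)
        assert w.mean() == pytest.approx(1.0)
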