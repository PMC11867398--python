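import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, special, stats

from leadchel import survival as sv

# samplers for the parameter-recovery checks, one per family
_TRUE_PARAMS = {
    "exponential": {"rate": 0.12},
    "weibull": {"shape": 1.4, "scale": 9.0},
    "gompertz": {"shape": 0.08, "rate": 0.05},
    "gamma": {"shape": 2.0, "rate": 0.25},
    "lognormal": {"meanlog": 2.0, "sdlog": 0.8},
    "loglogistic": {"shape": 2.2, "scale": 7.5},
    "generalized_gamma": {"mu": 2.0, "sigma": 0.7, "Q": 0.8},
}


def _sample(family, params, n, rng):
    if family == "exponential":
        return rng.exponential(1 / params["rate"], n)
    if family == "weibull":
        return params["scale"] * rng.weibull(params["shape"], n)
    if family == "gompertz":
        # inverse-CDF: S(t) = exp(-b/a (e^{at}-1))
        a, b = params["shape"], params["rate"]
        u = rng.random(n)
        return np.log(1 - a * np.log(u) / b) / a
    if family == "gamma":
        return rng.gamma(params["shape"], 1 / params["rate"], n)
    if family == "lognormal":
        return np.exp(rng.normal(params["meanlog"], params["sdlog"], n))
    if family == "loglogistic":
        return stats.fisk.rvs(params["shape"], scale=params["scale"],
                              size=n, random_state=rng)
    if family == "generalized_gamma":
        mu, sigma, q = params["mu"], params["sigma"], params["Q"]
        g = rng.gamma(q ** -2, 1.0, n)
        w = np.log(q * q * g) / q
        return np.exp(mu + sigma * w)
    raise ValueError(family)


class TestFitting:
    def test_exponential_mle_closed_form(self, rng):
        t = rng.exponential(5.0, 400)
        cens = t > 8.0
        times = np.minimum(t, 8.0)
        events = ~cens
        fit = sv.fit_parametric(times, events, "exponential")
        # closed-form censored-data MLE: events / total time at risk
        assert fit.params["rate"] == pytest.approx(
            events.sum() / times.sum(), rel=1e-4)

    def test_weibull_nests_exponential_likelihood(self, rng):
        t = rng.exponential(4.0, 300)
        events = np.ones_like(t, dtype=bool)
        exp_fit = sv.fit_parametric(t, events, "exponential")
        rate = exp_fit.params["rate"]
        # Weibull with shape=1, scale=1/rate has the same log-likelihood
        x = np.array([np.log(1.0), np.log(1.0 / rate)])
        nll_weib = sv._nll("weibull", x, t, events)
        assert -nll_weib == pytest.approx(exp_fit.loglik, rel=1e-8)

    def test_lognormal_recovery_with_censoring(self, rng):
        t = np.exp(rng.normal(2.0, 0.8, 2000))
        cens_at = np.quantile(t, 0.8)   # ~20% censoring
        times, events = np.minimum(t, cens_at), t <= cens_at
        fit = sv.fit_parametric(times, events, "lognormal")
        assert fit.params["meanlog"] == pytest.approx(2.0, abs=0.05)
        assert fit.params["sdlog"] == pytest.approx(0.8, abs=0.05)
        assert fit.n_events == int(events.sum())

    def test_information_criteria_identities(self, rng):
        t = rng.gamma(2.0, 4.0, 250)
        fit = sv.fit_parametric(t, np.ones_like(t, dtype=bool), "gamma")
        k, n = 2, 250
        assert fit.aic == pytest.approx(2 * k - 2 * fit.loglik)
        assert fit.bic == pytest.approx(k * np.log(n) - 2 * fit.loglik)

    def test_too_few_events_raises(self):
        with pytest.raises(ValueError, match="two events"):
            sv.fit_parametric([1.0, 2.0], [True, False], "exponential")

    @pytest.mark.parametrize("family", sv.FAMILIES)
    def test_parameter_recovery_within_three_se(self, family):
        rng = np.random.default_rng(hash(family) % 2 ** 31)
        true = _TRUE_PARAMS[family]
        t = _sample(family, true, 2000, rng)
        cens_at = np.quantile(t, 0.85)
        times, events = np.minimum(t, cens_at), t <= cens_at
        fit = sv.fit_parametric(times, events, family)
        assert fit.converged
        for name, value in true.items():
            se = fit.se.get(name)
            assert se is not None and se > 0
            assert abs(fit.params[name] - value) < 3 * se, (
                f"{family}.{name}: {fit.params[name]} vs {value} (se {se})")

    def test_matches_lifelines_estimates(self, rng):
        from lifelines import (ExponentialFitter, LogNormalFitter,
                               WeibullFitter)

        t = np.exp(rng.normal(1.5, 0.6, 800))
        cens_at = np.quantile(t, 0.75)
        times, events = np.minimum(t, cens_at), t <= cens_at
        pairs = [
            ("exponential", ExponentialFitter(),
             lambda ll: {"rate": 1 / ll.lambda_}),
            ("weibull", WeibullFitter(),
             lambda ll: {"shape": ll.rho_, "scale": ll.lambda_}),
            ("lognormal", LogNormalFitter(),
             lambda ll: {"meanlog": ll.mu_, "sdlog": ll.sigma_}),
        ]
        for family, fitter, extract in pairs:
            ours = sv.fit_parametric(times, events, family)
            fitter.fit(times, events)
            for name, value in extract(fitter).items():
                assert ours.params[name] == pytest.approx(value, rel=1e-3)
            assert ours.loglik == pytest.approx(fitter.log_likelihood_,
                                                rel=1e-6)


class TestSelection:
    def test_better_loglik_ranks_first(self):
        f1 = sv.ParametricFit("GF", "all", "exponential", {"rate": 1.0},
                              loglik=-100.0, aic=202.0, converged=True)
        f2 = sv.ParametricFit("GF", "all", "gompertz", {"shape": 0, "rate": 1},
                              loglik=-90.0, aic=184.0, converged=True)
        ranked, chosen = sv.select_model([f1, f2])
        assert chosen is f2 and ranked[0] is f2

    def test_override_beats_aic(self, rng):
        t = np.exp(rng.normal(2.0, 0.8, 1500))
        events = np.ones_like(t, dtype=bool)
        fits = sv.fit_all_families(t, events)
        ranked, chosen = sv.select_model(fits, override="gompertz")
        assert chosen.family == "gompertz"

    def test_lognormal_data_prefers_lognormal_over_exponential(self, rng):
        t = np.exp(rng.normal(2.0, 0.8, 3000))
        events = np.ones_like(t, dtype=bool)
        fits = {f.family: f for f in sv.fit_all_families(
            t, events, families=("exponential", "lognormal"))}
        assert fits["lognormal"].aic < fits["exponential"].aic

    def test_all_failed_raises(self):
        bad = sv.ParametricFit("GF", "all", "gamma", {}, converged=False)
        with pytest.raises(ValueError):
            sv.select_model([bad])


class TestExtrapolation:
    def test_exponential_closed_form(self):
        fit = sv.ParametricFit("GF", "all", "exponential", {"rate": 0.1})
        curve = sv.extrapolate_survival(fit, 3)
        np.testing.assert_allclose(
            curve.survival, [1, np.exp(-0.1), np.exp(-0.2), np.exp(-0.3)])

    @pytest.mark.parametrize("family", sv.FAMILIES)
    def test_survival_starts_at_one_and_decreases(self, family):
        fit = sv.ParametricFit("GF", "all", family, _TRUE_PARAMS[family])
        curve = sv.extrapolate_survival(fit, 40)
        assert curve.survival[0] == 1.0
        assert (np.diff(curve.survival) <= 1e-12).all()

    def test_lognormal_matches_quadrature_oracle(self):
        meanlog, sdlog = 1.2, 0.9
        fit = sv.ParametricFit("GF", "all", "lognormal",
                               {"meanlog": meanlog, "sdlog": sdlog})
        curve = sv.extrapolate_survival(fit, 5)
        for i in (1, 3, 5):
            integral, _ = integrate.quad(
                lambda x: stats.lognorm.pdf(x, sdlog, scale=np.exp(meanlog)),
                0, i)
            assert curve.survival[i] == pytest.approx(1 - integral, abs=1e-8)

    def test_gompertz_negative_shape_plateaus(self):
        fit = sv.ParametricFit("GF", "all", "gompertz",
                               {"shape": -0.3, "rate": 0.1})
        curve = sv.extrapolate_survival(fit, 60)
        plateau = np.exp(-0.1 / 0.3)
        assert curve.survival[-1] == pytest.approx(plateau, abs=1e-3)


class TestTransitionProbabilities:
    def test_geometric_decay_gives_constant_tp(self):
        curve = sv.SurvivalCurve(np.arange(3), np.array([1.0, 0.9, 0.81]))
        np.testing.assert_allclose(sv.survival_to_tp(curve), [0.1, 0.1])

    def test_exponential_memorylessness(self):
        lam = 0.25
        fit = sv.ParametricFit("GF", "all", "exponential", {"rate": lam})
        tp = sv.survival_to_tp(sv.extrapolate_survival(fit, 20))
        np.testing.assert_allclose(tp, 1 - np.exp(-lam), rtol=1e-12)

    def test_lognormal_tp_matches_fine_discretization(self):
        fit = sv.ParametricFit("GF", "all", "lognormal",
                               {"meanlog": 2.0, "sdlog": 1.0})
        tp = sv.survival_to_tp(sv.extrapolate_survival(fit, 2))
        # oracle: the same formula applied to a finely discretized curve,
        # composing the fine-step conditional survivals over each year
        t_fine = np.linspace(0, 2, 2001)
        s_fine = sv.survival_function("lognormal", t_fine,
                                      np.array([2.0, 1.0]))
        cond = s_fine[1:] / s_fine[:-1]
        for i in (1, 2):
            year = slice((i - 1) * 1000, i * 1000)
            assert tp[i - 1] == pytest.approx(1 - np.prod(cond[year]),
                                              rel=1e-9)

    def test_increasing_curve_rejected(self):
        with pytest.raises(ValueError):
            sv.SurvivalCurve(np.arange(3), np.array([1.0, 0.5, 0.6]))

    def test_underflowed_tail_warns_and_sets_tp_to_one(self):
        s = np.array([1.0, 1e-320, 0.0, 0.0])
        curve = sv.SurvivalCurve(np.arange(4), s)
        with pytest.warns(RuntimeWarning):
            tp = sv.survival_to_tp(curve)
        assert tp[-1] == 1.0

    @given(st.lists(st.floats(min_value=1e-6, max_value=0.999999),
                    min_size=1, max_size=40))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_round_trip_recovers_curve(self, tps):
        # any tp series in (0,1) defines a valid curve; converting back and
        # forth must be the identity to machine precision
        s = sv.tp_to_survival(np.array(tps))
        curve = sv.SurvivalCurve(np.arange(len(s)), s)
        tp_back = sv.survival_to_tp(curve)
        np.testing.assert_allclose(tp_back, tps, rtol=1e-12, atol=1e-12)
        assert ((tp_back >= 0) & (tp_back <= 1)).all()

    def test_gg_reduces_to_lognormal_and_gamma(self):
        # Q -> 0 lognormal; sigma = Q gamma(shape=1/Q^2): spot-check S(t)
        t = np.array([1.0, 5.0, 12.0])
        s_gg = sv.survival_function("generalized_gamma", t,
                                    np.array([2.0, 0.8, 1e-9]))
        s_ln = sv.survival_function("lognormal", t, np.array([2.0, 0.8]))
        np.testing.assert_allclose(s_gg, s_ln, rtol=1e-5)
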