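import numpy as np
import pytest

import ttbfrail as tb
from ttbfrail.frailty import FrailtySpec
from ttbfrail.hazards import WeibullHazard
from ttbfrail.ttb import (GradientError, InferenceError, MarginalCurvePair,
                          NoBenefitError, TTBRequest, Z_975, delta_ci,
                          estimate_ttb, mc_ci, survival_difference)


def exponential_crossing(delta, h0=0.2, h1=0.1):
    """Closed form for D(t) = x - x^2 = delta, x = exp(-h1 t) (larger root)."""
    x = (1 + np.sqrt(1 - 4 * delta)) / 2
    return -np.log(x) / h1


@pytest.fixture
def exp_curves():
    return MarginalCurvePair(
        {0: WeibullHazard(0.2, 1.0), 1: WeibullHazard(0.1, 1.0)},
        FrailtySpec("none"))


def test_difference_zero_at_time_zero(exp_curves):
    assert survival_difference(exp_curves, 0.0) == pytest.approx(0.0, abs=0)


def test_difference_closed_form_value(exp_curves):
    t = np.log(2) / 0.1
    assert survival_difference(exp_curves, t)[0] == pytest.approx(0.25,
                                                                  abs=1e-12)


def test_identical_arms_difference_is_zero():
    curves = MarginalCurvePair(
        {0: WeibullHazard(0.3, 1.2), 1: WeibullHazard(0.3, 1.2)},
        FrailtySpec("gamma", 0.7))
    ts = np.linspace(0.0, 10.0, 50)
    np.testing.assert_allclose(curves.difference(ts), 0.0, atol=1e-15)
    with pytest.raises(NoBenefitError):
        estimate_ttb(curves, TTBRequest(0.01, t_max=10.0))


@pytest.mark.parametrize("delta", [0.01, 0.05, 0.1, 0.2])
def test_estimate_ttb_matches_quadratic_closed_form(exp_curves, delta):
    est = estimate_ttb(exp_curves, TTBRequest(delta, t_max=40.0))
    assert est.tau_hat == pytest.approx(exponential_crossing(delta), abs=1e-5)


def test_estimate_ttb_no_benefit_beyond_max_difference(exp_curves):
    with pytest.raises(NoBenefitError) as exc:
        estimate_ttb(exp_curves, TTBRequest(0.3, t_max=60.0))
    assert exc.value.max_difference == pytest.approx(0.25, abs=1e-4)


def test_ttb_monotone_in_threshold():
    rng = np.random.default_rng(99)
    for _ in range(20):
        alpha0 = rng.uniform(0.05, 0.5)
        gamma = rng.uniform(0.8, 1.8)
        hr = rng.uniform(0.5, 0.9)
        theta = rng.uniform(0.0, 1.0)
        curves = MarginalCurvePair(
            {0: WeibullHazard(alpha0, gamma), 1: WeibullHazard(alpha0 * hr, gamma)},
            FrailtySpec("gamma", theta))
        ts = np.linspace(1e-4, 30.0, 4000)
        dmax = curves.difference(ts).max()
        d1, d2 = 0.3 * dmax, 0.7 * dmax
        t1 = estimate_ttb(curves, TTBRequest(d1, t_max=30.0)).tau_hat
        t2 = estimate_ttb(curves, TTBRequest(d2, t_max=30.0)).tau_hat
        assert t1 <= t2 + 1e-9


def test_estimate_ttb_matches_dense_grid_oracle():
    rng = np.random.default_rng(5)
    for _ in range(10):
        alpha0 = rng.uniform(0.05, 0.5)
        gamma = rng.uniform(0.8, 1.8)
        hr = rng.uniform(0.5, 0.9)
        theta = rng.uniform(0.0, 1.0)
        curves = MarginalCurvePair(
            {0: WeibullHazard(alpha0, gamma), 1: WeibullHazard(alpha0 * hr, gamma)},
            FrailtySpec("gamma", theta))
        t_max = 30.0
        ts = np.linspace(0.0, t_max, 1_000_001)[1:]
        f = curves.difference(ts) - 0.02
        hits = np.flatnonzero(f >= 0)
        if hits.size == 0:
            continue
        i = hits[0]
        if i == 0:
            oracle = ts[0]
        else:  # linear interpolation inside the bracketing cell
            oracle = ts[i - 1] + (ts[i] - ts[i - 1]) * (-f[i - 1]) / (
                f[i] - f[i - 1])
        est = estimate_ttb(curves, TTBRequest(0.02, t_max=t_max, tol=1e-6))
        assert est.tau_hat == pytest.approx(oracle, abs=2e-6)


def test_delta_ci_zero_covariance_degenerates(toy_exponential_results):
    res = toy_exponential_results
    res.cov = np.zeros((2, 2))
    est = delta_ci(res, TTBRequest(0.05, t_max=20.0))
    assert est.ci[0] == pytest.approx(est.tau_hat)
    assert est.ci[1] == pytest.approx(est.tau_hat)


def test_delta_ci_back_transform(toy_exponential_results):
    est = delta_ci(toy_exponential_results, TTBRequest(0.05, t_max=20.0))
    se = np.sqrt(est.var_log_tau)
    assert est.ci[0] == pytest.approx(est.tau_hat * np.exp(-Z_975 * se))
    assert est.ci[1] == pytest.approx(est.tau_hat * np.exp(Z_975 * se))
    assert est.ci[0] <= est.tau_hat <= est.ci[1]
    # known variance: var = g' Sigma g with Sigma = 0.04 I
    g = np.asarray(est.grad_log_tau)
    assert est.var_log_tau == pytest.approx(0.04 * float(g @ g), rel=1e-10)


def test_delta_gradient_matches_implicit_function_oracle(
        toy_exponential_results):
    """FD gradient of ln(tau) vs the implicit-function form
    g_k = -(dD/dphi_k) / (D'(tau) * tau) for exponential arms."""
    est = delta_ci(toy_exponential_results, TTBRequest(0.05, t_max=20.0))
    a0, a1 = 0.2, 0.1
    tau = est.tau_hat
    dD = np.array([a0 * tau * np.exp(-a0 * tau),
                   -a1 * tau * np.exp(-a1 * tau)])   # wrt ln a0, ln a1
    Dp = a0 * np.exp(-a0 * tau) - a1 * np.exp(-a1 * tau)
    oracle = -dD / (Dp * tau)
    np.testing.assert_allclose(est.grad_log_tau, oracle, rtol=1e-3)


def test_delta_ci_gradient_error_when_crossing_fragile(
        toy_exponential_results):
    # Delta just below the analytic maximum 0.25: any perturbation that
    # weakens the treatment effect loses the crossing
    with pytest.raises((GradientError, NoBenefitError)):
        delta_ci(toy_exponential_results, TTBRequest(0.2499999, t_max=60.0))


def test_mc_ci_zero_covariance_degenerates(toy_exponential_results):
    res = toy_exponential_results
    res.cov = np.zeros((2, 2))
    est = mc_ci(res, TTBRequest(0.05, t_max=20.0), B=200, seed=3)
    assert est.ci[0] == pytest.approx(est.tau_hat, rel=1e-6)
    assert est.ci[1] == pytest.approx(est.tau_hat, rel=1e-6)


def test_mc_ci_deterministic_under_seed(toy_exponential_results):
    req = TTBRequest(0.05, t_max=20.0)
    a = mc_ci(toy_exponential_results, req, B=300, seed=7)
    b = mc_ci(toy_exponential_results, req, B=300, seed=7)
    assert a.tau_hat == b.tau_hat
    assert a.ci == b.ci


def test_mc_median_comparable_to_delta_point(toy_exponential_results):
    res = toy_exponential_results
    res.cov = np.eye(2) * 0.005
    req = TTBRequest(0.05, t_max=40.0)
    point = delta_ci(res, req)
    mc = mc_ci(res, req, B=2000, seed=11)
    se_mc = np.std([np.log(mc.ci[0]), np.log(mc.ci[1])]) / np.sqrt(2000)
    # medians agree within a couple of MC standard errors on the log scale
    assert abs(np.log(mc.tau_hat) - np.log(point.tau_hat)) < max(
        2 * 1.25 * np.sqrt(point.var_log_tau / 2000), 0.02)
    assert mc.ci[0] <= mc.tau_hat <= mc.ci[1]


def test_mc_ci_counts_non_crossing_draws(toy_exponential_results):
    res = toy_exponential_results
    res.cov = np.eye(2) * 0.01
    est = mc_ci(res, TTBRequest(0.24, t_max=80.0), B=200, seed=21)
    assert est.mc_draws["non_crossing"] > 0
    assert np.isfinite(est.tau_hat)


def test_mc_ci_error_when_mostly_non_crossing(toy_exponential_results):
    res = toy_exponential_results
    res.cov = np.eye(2) * 0.0025
    # 0.26 exceeds the analytic maximum difference 0.25, so almost no
    # parameter draw can produce a crossing
    with pytest.raises(InferenceError):
        mc_ci(res, TTBRequest(0.26, t_max=80.0), B=200, seed=2)


def test_request_validation():
    with pytest.raises(ValueError):
        TTBRequest(1.5)
    with pytest.raises(ValueError):
        TTBRequest(0.0)
    with pytest.raises(ValueError):
        TTBRequest(0.05, t_max=-1.0)


def test_results_ttb_api_uses_data_horizon(wf_results):
    est = wf_results.ttb(0.005, method="delta")
    assert est.crossing_found
    assert est.ci[0] < est.tau_hat < est.ci[1]
    est2 = wf_results.ttb(0.002, method="point")
    assert est2.tau_hat <= est.tau_hat
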