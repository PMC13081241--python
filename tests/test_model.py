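import numpy as np
import pandas as pd
import pytest
from scipy import integrate

import ttbfrail as tb
from ttbfrail.frailty import FrailtySpec, HermiteRule
from ttbfrail.hazards import WeibullHazard
from ttbfrail.model import (ModelSpec, SharedFrailtySurvivalModel,
                            cluster_loglik, select_smoothing)


EXP1 = WeibullHazard(1.0, 1.0)          # unit exponential baseline


def test_cluster_loglik_single_censored_subject():
    # d=0, A=H=1, gamma theta=1: -(1/theta) ln(1 + theta A) = -ln 2
    ll = cluster_loglik([1.0], [0], [0], {0: EXP1, 1: EXP1},
                        FrailtySpec("gamma", 1.0))
    assert ll == pytest.approx(-np.log(2.0))


def test_cluster_loglik_single_event_matches_integral_oracle():
    # event at t=1, h==1 so H=1; marginal likelihood is
    # int_0^inf  w e^{-w} * e^{-w} dw = 1/4 under Gamma(1,1) frailty
    ll = cluster_loglik([1.0], [1], [0], {0: EXP1, 1: EXP1},
                        FrailtySpec("gamma", 1.0))
    oracle, _ = integrate.quad(lambda w: np.exp(-w) * w * np.exp(-w), 0, np.inf)
    assert oracle == pytest.approx(0.25)
    assert ll == pytest.approx(np.log(oracle))


def test_cluster_loglik_tiny_theta_equals_no_frailty():
    t = [0.5, 1.2, 2.0]
    d = [1, 0, 1]
    a = [0, 1, 0]
    hz = {0: WeibullHazard(0.4, 1.2), 1: WeibullHazard(0.25, 1.2)}
    tiny = cluster_loglik(t, d, a, hz, FrailtySpec("gamma", 1e-10))
    none = cluster_loglik(t, d, a, hz, FrailtySpec("none"))
    assert tiny == pytest.approx(none, abs=1e-6)


def test_cluster_loglik_lognormal_matches_integral_oracle():
    t = [0.8, 1.5]
    d = [1, 1]
    a = [0, 0]
    theta = 0.6
    hz = {0: WeibullHazard(0.5, 1.3), 1: WeibullHazard(0.3, 1.3)}
    ll = cluster_loglik(t, d, a, hz, FrailtySpec("lognormal", theta),
                        HermiteRule(60))
    H = sum(hz[0].cumulative_hazard(ti) for ti in t)
    P = sum(np.log(hz[0].hazard(ti)) for ti in t)
    sd = np.sqrt(theta)
    oracle, _ = integrate.quad(
        lambda z: np.exp(-z**2 / (2 * theta)) / np.sqrt(2 * np.pi * theta)
        * np.exp(2 * z + P - np.exp(z) * H),
        -12 * sd, 12 * sd, epsabs=1e-14, limit=400)
    assert ll == pytest.approx(np.log(oracle), abs=1e-8)


def test_loglik_adds_over_clusters(sim_small):
    model = SharedFrailtySurvivalModel(sim_small.data, frailty="gamma")
    phi = model._start_values()
    total = model.loglike(phi)
    parts = 0.0
    for cid in sim_small.data.cluster_ids:
        sub = tb.ClusteredSurvivalData(
            sim_small.data.frame[sim_small.data.frame["cluster"] == cid],
            validate=False)
        hz = model.hazards_from_phi(phi)
        parts += cluster_loglik(sub.time, sub.event, sub.arm, hz,
                                model.frailty_from_phi(phi), model.rule)
    assert total == pytest.approx(parts, rel=1e-10)


def test_penalty_zero_cases(sim_small):
    model = SharedFrailtySurvivalModel(sim_small.data, baseline="pms",
                                       frailty="gamma", n_basis=5)
    phi = model._start_values()
    assert model.penalized_loglike(phi, 0.0) == model.loglike(phi)
    # zero spline coefficients: penalty vanishes for any weight
    assert model.penalized_loglike(phi, 50.0) == pytest.approx(
        model.loglike(phi))
    phi2 = phi.copy()
    # non-constant coefficients (a constant vector lies in the null space
    # of the second-order difference penalty)
    phi2[1:1 + 5] = [0.3, -0.2, 0.5, 0.0, 0.4]
    assert model.penalized_loglike(phi2, 50.0) < model.loglike(phi2)


def test_fit_recovers_weibull_gamma_truth():
    cfg = tb.ScenarioConfig(
        n_total=10_000, n_clusters=100,
        arm0_hazard=WeibullHazard(0.1, 1.3), arm1_hazard=WeibullHazard(0.07, 1.3),
        frailty=FrailtySpec("gamma", 0.5), seed=17)
    sim = tb.generate(cfg)
    res = SharedFrailtySurvivalModel(sim.data, frailty="gamma").fit(seed=1)
    est = dict(zip(res.layout, res.params))
    assert est["arm0.log_alpha"] == pytest.approx(np.log(0.1), abs=0.15)
    assert est["arm0.log_gamma"] == pytest.approx(np.log(1.3), abs=0.1)
    assert est["arm1.log_alpha"] == pytest.approx(np.log(0.07), abs=0.15)
    assert res.theta == pytest.approx(0.5, abs=0.2)


def test_no_frailty_loglik_is_subject_sum(sim_small):
    model = SharedFrailtySurvivalModel(sim_small.data, frailty="none")
    res = model.fit(seed=0, n_starts=1)
    hz = res.hazards()
    t, d, a = sim_small.data.time, sim_small.data.event, sim_small.data.arm
    closed = 0.0
    for arm in (0, 1):
        m = a == arm
        closed += np.sum(d[m] * hz[arm].log_hazard(t[m]))
        closed -= np.sum(hz[arm].cumulative_hazard(t[m]))
    assert res.llf == pytest.approx(closed, rel=1e-8)


def test_zero_events_rejected(toy_frame):
    data = tb.ClusteredSurvivalData(toy_frame.assign(event=0))
    with pytest.raises(ValueError, match="zero events"):
        SharedFrailtySurvivalModel(data, frailty="gamma").fit()


def test_wald_se_matches_exponential_closed_form():
    """No-frailty exponential fit: SE(ln alpha_a) ~= 1/sqrt(#events in arm)."""
    cfg = tb.ScenarioConfig(
        n_total=4000, n_clusters=40,
        arm0_hazard=WeibullHazard(0.3, 1.0), arm1_hazard=WeibullHazard(0.2, 1.0),
        frailty=FrailtySpec("none"), seed=5)
    sim = tb.generate(cfg)
    res = SharedFrailtySurvivalModel(sim.data, frailty="none",
                                     fix_shape=True).fit(seed=0, n_starts=1)
    se = res.bse()
    for arm in (0, 1):
        d = sim.data.event[sim.data.arm == arm].sum()
        assert se[arm] == pytest.approx(1.0 / np.sqrt(d), rel=0.05)


def test_gradient_small_and_covariance_sane(wf_results):
    assert wf_results.convergence["grad_max_scaled"] < 1e-4
    cov = wf_results.cov_params()
    np.testing.assert_allclose(cov, cov.T, atol=1e-10)
    assert np.all(np.diag(cov) >= 0)


def test_gamma_and_lognormal_agree_in_frailty_free_limit(sim_small):
    """At theta -> 0 both families' likelihoods coincide with 'none'."""
    mg = SharedFrailtySurvivalModel(sim_small.data, frailty="gamma")
    ml = SharedFrailtySurvivalModel(sim_small.data, frailty="lognormal")
    mn = SharedFrailtySurvivalModel(sim_small.data, frailty="none")
    phi_base = mn._start_values()
    phi = np.r_[phi_base, np.log(1e-12)]
    assert mg.loglike(phi) == pytest.approx(mn.loglike(phi_base), abs=1e-6)
    assert ml.loglike(phi) == pytest.approx(mn.loglike(phi_base), abs=1e-6)


def test_results_json_round_trip(wf_results):
    back = tb.SharedFrailtyResults.from_json(wf_results.to_json())
    np.testing.assert_allclose(back.params, wf_results.params)
    np.testing.assert_allclose(back.cov, wf_results.cov)
    ts = np.linspace(0.1, 4.0, 20)
    np.testing.assert_allclose(back.curves().difference(ts),
                               wf_results.curves().difference(ts))


def test_summary_mentions_frailty_test(wf_results):
    text = wf_results.summary()
    assert "frailty variance theta" in text
    assert "log_theta" in text


def test_select_smoothing_single_grid_value(sim_small):
    lam = select_smoothing(sim_small.data, baseline="pms", grid=[3.0])
    assert lam == 3.0


def test_select_smoothing_needs_enough_clusters(toy_frame):
    data = tb.ClusteredSurvivalData(toy_frame)
    with pytest.raises(ValueError, match="clusters"):
        select_smoothing(data, baseline="pms", grid=[0.1, 1.0])


def test_smoothing_prefers_more_penalty_for_constant_hazard():
    """Constant-hazard truth tolerates (and benefits from) heavy smoothing;
    a sharply varying hazard should select a smaller penalty on average."""
    grid = [1e-2, 1.0, 1e2]
    lam_flat, lam_wiggly = [], []
    for seed in range(3):
        flat = tb.generate(tb.ScenarioConfig(
            n_total=600, n_clusters=10,
            arm0_hazard=WeibullHazard(0.5, 1.0), arm1_hazard=WeibullHazard(0.5, 1.0),
            frailty=FrailtySpec("none"), seed=seed))
        wiggly = tb.generate(tb.ScenarioConfig(
            n_total=600, n_clusters=10,
            arm0_hazard=tb.PiecewiseWeibullHazard(1.5, 3.0, 0.1, 0.6, 1.0),
            arm1_hazard=tb.PiecewiseWeibullHazard(1.5, 3.0, 0.1, 0.6, 1.0),
            frailty=FrailtySpec("none"), seed=seed))
        lam_flat.append(select_smoothing(flat.data, baseline="pms",
                                         frailty="none", n_basis=5,
                                         grid=grid, seed=seed))
        lam_wiggly.append(select_smoothing(wiggly.data, baseline="pms",
                                           frailty="none", n_basis=5,
                                           grid=grid, seed=seed))
    assert np.mean(np.log(lam_flat)) >= np.mean(np.log(lam_wiggly))


def test_model_spec_names():
    assert ModelSpec("weibull", "none").name == "WnoF"
    assert ModelSpec("weibull", "gamma").name == "WF"
    assert ModelSpec("ptprs", "gamma").name == "PTPRSF"
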