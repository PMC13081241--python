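# ttbfrail

Time-to-benefit estimation from clustered (multicenter) survival data with
shared-frailty marginal survival models.

## The problem

The **time to benefit (TTB)** answers "how long must a patient wait before a
treatment's benefit becomes clinically meaningful?" — a question central to
treatment decisions for older adults and high-risk populations, where a
therapy whose benefit emerges only after several years may not be worth its
immediate burden. Formally, with marginal survival functions S₁(t)
(treatment) and S₀(t) (control) and a prespecified absolute risk reduction
threshold Δ,

    τ = inf{ t > 0 : S₁(t) − S₀(t) ≥ Δ }.

τ is an *implicit, threshold-crossing* estimand: it depends on the entire
shape of both survival curves, so it is unusually sensitive to baseline
hazard specification — and, in multicenter trials, to unobserved
between-site heterogeneity.

`ttbfrail` estimates τ coherently on the marginal (population-averaged)
scale. Each subject i in center j under arm a has conditional hazard

    h_ija(t) = ω_j · h_0a(t),

where ω_j is a center-level shared frailty (Gamma(1/θ, 1/θ), mean 1 and
variance θ; or ln ω ~ N(0, θ)) and h_0a is an arm-specific baseline hazard —
parametric Weibull (h = αγt^{γ−1}) or a flexible spline log-hazard
(ln h = β₀ + Σ_k β_k B_k(t); penalized M-splines, thin-plate regression
splines, or natural cubic splines). The marginal survival averages the
conditional survival over the frailty — for Gamma frailty in closed form,

    S_a(t) = (1 + θ H_0a(t))^{−1/θ},

and by Gauss–Hermite quadrature for log-normal frailty. τ̂ is found by
root-finding on Ŝ₁ − Ŝ₀, and its uncertainty is quantified on the ln τ scale
two ways:

* **Delta method**: Var(ln τ̂) ≈ gᵀ Σ̂_φ g with g = ∂ln τ̂/∂φ̂ obtained by
  perturbing the full fitted parameter vector and re-solving the crossing;
* **Monte Carlo**: draw φ^(b) ~ MVN(φ̂, Σ̂_φ), re-solve τ^(b) per draw, and
  report the median and empirical 2.5%/97.5% quantiles.

A full simulation harness generates clustered data under configurable
truths (Weibull or piecewise-Weibull with a change point), calibrates
censoring to a target rate, computes the true marginal τ, and scores
estimators by log-scale bias/MAE/RMSE and interval coverage
(CP/OLLP/OULP/length).

## Worked example

Simulate a multicenter trial (100 sites, 5,000 subjects, Weibull baselines,
gamma frailty θ = 0.5, ~90% censoring), fit the Weibull shared-frailty
model, and estimate the TTB at three thresholds:

```python
import ttbfrail as tb

sim = tb.generate(tb.scenario_one(n_total=5000, n_clusters=100,
                                  censor_target=0.9, seed=42))
model = tb.SharedFrailtySurvivalModel(sim.data, baseline="weibull",
                                      frailty="gamma")
res = model.fit(seed=0)
print(res.summary())
for d in (0.002, 0.005, 0.010):
    est = res.ttb(d, method="delta")
    print(d, est.tau_hat, est.ci)
```

which prints

```
Shared-frailty survival model
  baseline: weibull   frailty: gamma
  log-likelihood: -2248.9201   penalized: -2248.9201
  converged: True   iterations: 17

  parameter             estimate     std err         z     P>|z|
  arm0.log_alpha         -4.0171      0.1405   -28.595    0.0000
  arm0.log_gamma          0.2332      0.0544     4.290    0.0000
  arm1.log_alpha         -4.5075      0.1669   -27.007    0.0000
  arm1.log_gamma          0.3371      0.0621     5.432    0.0000
  log_theta              -0.7365      0.2092    -3.521    0.0004

  frailty variance theta = 0.4788 (SE 0.1002), Wald test of ln theta: z = -3.521, p = 0.0004305
ARR 0.002: delta tau=0.316 CI=(0.132,0.757)
ARR 0.005: delta tau=0.739 CI=(0.332,1.646)
ARR 0.010: delta tau=1.468 CI=(0.697,3.093)
```

The frailty variance is recovered near its true value 0.5 and its Wald test
flags significant between-site heterogeneity. The true marginal TTBs under
this generating mechanism are 0.498, 1.018 and 1.769: each falls inside the
corresponding interval. `res.ttb(d, method="mc", B=1000, seed=1)` gives the
Monte Carlo alternative.

The same workflow is available from the shell:

```sh
ttbfrail fit trial.csv --baseline weibull --frailty gamma --out model.json
ttbfrail ttb model.json --arr 0.005 --arr 0.010 --method mc --draws 1000
ttbfrail simulate scenario.yaml --model WF --model NCS --replicates 100
```

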