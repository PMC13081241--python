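# Methods

## Estimand

The time to benefit is τ = inf{t > 0 : S₁(t) − S₀(t) ≥ Δ}, with S_a the
*marginal* survival function of arm a and Δ an absolute risk reduction
threshold in probability units (package defaults: Δ ∈ {0.002, 0.005,
0.010}). Defining τ marginally — averaging over the cluster frailty before
taking the difference — keeps the estimand aligned with its
population-level clinical reading; the conditional (frailty-fixed)
difference answers a different question. The first crossing is returned
even when the difference later dips back below Δ; re-crossings are not
reported.

## Model

Subjects are nested in clusters (trial sites). Given a cluster frailty
ω_j > 0, subject hazards are h(t) = ω_j h_0a(t) with one baseline per arm
and no covariates (the two-arm randomized setting). Supported baselines:

* **Weibull**: h(t) = αγt^{γ−1}, H(t) = αt^γ.
* **Spline log-hazard**: ln h(t) = β₀ + Σ_{k=1}^K β_k B_k(t) with K = 6 by
  default. Three bases: penalized M-splines (order-3 M-spline basis,
  second-order difference penalty), penalized thin-plate regression
  splines (eigen-truncated |t − t_k|³ radial basis, mgcv-style constraint
  absorption, thin-plate penalty; columns rescaled to unit RMS at the
  knots for optimizer conditioning), and natural cubic splines
  (unpenalized). Because all three sit on the log-hazard scale, positivity
  comes from the exponential link and no coefficient constraints are
  needed — M-spline coefficients in particular are *not* constrained
  nonnegative. Interior knots sit at event-time quantiles, boundaries at
  the observed follow-up range, and the log-hazard is continued linearly
  beyond the boundary (the natural tail behavior for NCS; a deliberate
  choice for the others, since threshold root-finding may probe slightly
  past the last event).

Frailty families: gamma (ω ~ Gamma(1/θ, 1/θ), mean 1, variance θ),
log-normal (ln ω ~ N(0, θ), median 1 — used exactly as stated, with
E[ω] = e^{θ/2}; no mean-one renormalization, so cross-family comparisons
at equal θ are not mean-matched), or none (ω ≡ 1).

Marginal survival is the frailty Laplace transform at H(t): the gamma
closed form (1 + θH)^{−1/θ} is evaluated as exp(−log1p(θH)/θ), which is
accurate through θ → 0; the log-normal expectation uses a 40-node
Gauss–Hermite rule. The 40-node rule is accurate to better than 1e−8 for
θ ≤ 1 and degrades to ~1e−7–1e−6 around θ = 2; raise `hermite_nodes` for
extreme heterogeneity.

## Likelihood and fitting

The cluster-integrated log-likelihood uses, per cluster, d = Σδ_i,
A = Σ H(t_i), P = Σ_{δ=1} ln h(t_i):

* gamma: P + d lnθ + lnΓ(1/θ + d) − lnΓ(1/θ) − (1/θ + d) ln(1 + θA),
  computed for θ < 1e−6 via the expansion Σ_{i<d} log1p(iθ) ≈ θd(d−1)/2 to
  avoid cancellation of lnΓ at huge arguments;
* log-normal: ln ∫ φ(z; 0, θ) exp(dz + P − e^z A) dz by Gauss–Hermite with
  log-sum-exp stabilization;
* none: P − A.

All positivity-constrained parameters are log-transformed, so the stacked
vector φ = (arm-0 baseline, arm-1 baseline, ln θ) is unconstrained; the
covariance and the Delta method operate on this working scale (which also
improves the normal approximation — interval math happens on ln τ).
Optimization is L-BFGS-B with finite-difference gradients and multi-start
(a moment-based exponential start plus two seeded jittered starts by
default; this guards against the bimodal likelihoods that Weibull +
log-normal frailty can produce). Spline cumulative hazards inside the
likelihood use fixed per-subject Gauss–Legendre panels (24 nodes); the
public `cumulative_hazard` uses adaptive quadrature to relative tolerance
≤ 1e−8.

Σ̂_φ is the inverse of the negative numerical Hessian of the *penalized*
log-likelihood at the optimum (observed information, not a sandwich; for
penalized fits the intervals are therefore approximate Bayesian-type
intervals). Non-positive-definite information triggers eigenvalue clipping
at a 1e−10 relative floor, recorded in the convergence diagnostics and
warned about — this occurs routinely for flexible spline fits with sparse
events in the tails.

Spline penalty weights λ_s are chosen by 5-fold cluster-level
cross-validation of the held-out unpenalized log-likelihood (folds at
cluster level to respect within-cluster dependence; a single λ shared by
both arms), over a 10-point log-spaced grid in [1e−4, 1e3] by default.
Smoothing is selected on a coarse fit first, then the model is refit at
the selected weight; `fit(smoothing=...)` also accepts a fixed value,
which the simulation harness uses to keep large replicate studies
tractable.

## TTB inference

Point estimate: D(t) − Δ is scanned on a uniform 2,048-point grid over
(0, t_max] (t_max defaults to 1.5 × the last observed follow-up), and the
first negative-to-nonnegative interval is refined by bracketed Brent
root-finding to a 1e−6 time-unit tolerance. The grid-then-bracket design
guarantees the *first* crossing; a bare Newton/Brent start could land on a
later root.

Delta method: g = ∂ln τ̂/∂φ is computed by central finite differences
(step 1e−5 · max(1, |φ_k|)), re-solving the crossing per perturbation at a
much tighter internal tolerance (1e−12) so root error does not contaminate
the quotient; Var(ln τ̂) = gᵀΣ̂g and the 95% CI is exp(ln τ̂ ∓ 1.959964·SE).
A perturbation that loses the crossing raises an error advising the MC
method.

Monte Carlo: φ^(b) ~ MVN(φ̂, Σ̂_φ) via an eigenvalue-clipped Cholesky
factor; τ^(b) re-solved per draw; point estimate = median, CI = empirical
2.5%/97.5% quantiles (linear-interpolation definition). Draws with no
crossing are excluded from the quantiles and counted in the result; more
than 50% non-crossing draws is an inference error. B = 1000 by default
(2000 optional).

## Synthetic data and study conditions

The generator draws one frailty per cluster, assigns arms 1:1 within each
cluster by deterministic alternation (reproducibility over random
assignment), and inverts the conditional cumulative hazard exactly:
T = H_a^{−1}(E/ω), E ~ Exp(1), with closed-form inverses for Weibull and
piecewise Weibull. Censoring times are Weibull with a scale calibrated by
monotone bisection on a fixed-seed 200,000-draw Monte Carlo estimate of
P(C < T); target 0 means no censoring.

Preset conditions: **Scenario I** has Weibull baselines in both arms
(λ₀ = 0.018, λ₁ = 0.013, ρ = 1.3, gamma frailty θ = 0.5), giving
five-year cumulative event fractions near 13%/10% and true TTBs of
0.50/1.02/1.77 at the three default thresholds — event-rate magnitudes
typical of large cardiovascular prevention trials. **Scenario II** keeps
the control arm and gives the treatment arm a piecewise-Weibull hazard
equal to control on [0, 1] and dropping afterwards (change point 1.0 time
units, configurable): no early benefit, and no single Weibull can match
the shape. A synthetic multicenter preset (`sprint_like_config`: 102
clusters, 9,361 subjects, ~7–9% events over a ~5-unit horizon) exists for
documentation and smoke tests only.

What passing tests show — and do not. The generator emulates clustered
event times with multiplicative heterogeneity, balanced arms, and
independent Weibull censoring. It does not emulate covariate-driven risk
variation, informative censoring, staggered entry, or site-size imbalance
beyond remainder spreading; conclusions about those features of real
trials do not follow from these tests. Replicate studies in the test suite
and acceptance script run at reduced problem sizes (e.g. 50 clusters × 40
subjects, 100–200 replicates, B = 500) — chosen as the smallest sizes at
which the statistical contrasts of interest are resolvable, and verified
to preserve them: interval coverage near nominal under correct
specification, and under the Scenario-II change point a larger absolute
log-scale TTB bias for the Weibull fit than for the spline fit. Heavy
censoring (90%) is used for the misspecification study because it bounds
the follow-up horizon the way an administratively censored trial would;
without censoring, event-time quantile knots spread over an unrealistically
long tail and starve the spline of resolution where the TTB lives.

## Evaluation metrics

All metrics operate on e_r = ln τ̂_r − ln τ_true: bias, MAE, RMSE for point
estimation; CP, OLLP, OULP (which partition 1) and mean log interval
length for 95% intervals. Replicates whose fit or crossing failed are
excluded and counted in `n_failed` — transparency over imputation; CP
denominators therefore include only replicates with an interval.

## Known limitations

* No covariates, left truncation, interval censoring, or time-varying
  effects; two arms only.
* Spline fits with very few events can yield flat likelihood directions;
  the PD-repaired covariance then widens MC intervals rather than failing.
* Gauss–Hermite accuracy degrades for log-normal θ ≳ 2 at the default 40
  nodes.
* The smoothing selector is cross-validation only (no REML), and λ_s is
  shared across arms.
* True TTB values for a generating mechanism are computed by the same
  root-finding machinery as the estimator (on exact curves); they are
  verified against closed forms where those exist.
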