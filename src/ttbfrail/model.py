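"""Shared-frailty survival model: marginal likelihood, fitting, results.

The model has one baseline hazard per treatment arm (Weibull or a spline
log-hazard) and a single cluster-level frailty shared across arms. The
cluster-integrated log-likelihood marginalizes the frailty analytically
(gamma) or by Gauss-Hermite quadrature (log-normal). All positivity-
constrained parameters are estimated on the log scale, so the stacked
parameter vector phi is unconstrained:

    phi = (arm-0 baseline params, arm-1 baseline params, ln theta)

``SharedFrailtySurvivalModel.fit()`` maximizes the (penalized) likelihood
by quasi-Newton iteration with multi-start and returns a
``SharedFrailtyResults`` carrying phi-hat, its covariance (inverse negative
Hessian of the penalized log-likelihood), and diagnostics. The covariance
feeds both Delta-method and Monte Carlo inference for the time to benefit.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import optimize
from scipy.special import gammaln, logsumexp
from statsmodels.tools.numdiff import approx_fprime, approx_hess3

from .data import ClusteredSurvivalData
from .frailty import FrailtySpec, HermiteRule
from .hazards import (QuadratureGrid, SplineLogHazard, WeibullHazard,
                      build_spline_basis, spline_basis_from_dict)

_SPLINE_FAMILIES = ("pms", "ptprs", "ncs")
_BAD_LL = -1e12


class ConvergenceError(RuntimeError):
    """Optimizer failed; carries the best iterate and diagnostics."""

    def __init__(self, message, best_params=None, diagnostics=None):
        super().__init__(message)
        self.best_params = best_params
        self.diagnostics = diagnostics or {}


@dataclass
class ModelSpec:
    """Declarative model choice: baseline family, frailty family, smoothing.

    ``baseline_family`` in {'weibull', 'pms', 'ptprs', 'ncs'};
    ``frailty_family`` in {'gamma', 'lognormal', 'none'}. ``smoothing`` is a
    fixed penalty weight, or 'cv' for cluster-level cross-validation
    (splines only; ignored for Weibull/NCS whose penalty is zero).
    """

    baseline_family: str = "weibull"
    frailty_family: str = "gamma"
    n_basis: int = 6
    smoothing: float | str = 0.0
    fix_shape: bool = False
    name: str | None = None

    def __post_init__(self):
        if self.baseline_family not in ("weibull",) + _SPLINE_FAMILIES:
            raise ValueError(f"unknown baseline family {self.baseline_family!r}")
        if self.frailty_family not in ("gamma", "lognormal", "none"):
            raise ValueError(f"unknown frailty family {self.frailty_family!r}")
        if self.name is None:
            tag = {"weibull": "W", "pms": "PMS", "ptprs": "PTPRS",
                   "ncs": "NCS"}[self.baseline_family]
            suffix = "noF" if self.frailty_family == "none" else "F"
            self.name = tag + suffix


# ---------------------------------------------------------------------------
# Cluster-level log-likelihood


def _cluster_terms_loglik(d, A, P, frailty: FrailtySpec,
                          rule: HermiteRule | None = None):
    """Vector of per-cluster marginal log-likelihood contributions.

    d: event counts, A: summed cumulative hazards, P: summed log-hazards at
    event times — one entry per cluster.
    """
    d = np.asarray(d, dtype=float)
    A = np.asarray(A, dtype=float)
    P = np.asarray(P, dtype=float)
    theta = frailty.theta
    if frailty.family == "none" or theta == 0.0:
        return P - A
    if frailty.family == "gamma":
        if theta < 1e-6:
            # d*ln(theta) + lnGamma(1/theta + d) - lnGamma(1/theta)
            #   = sum_{i<d} log1p(i*theta) ~= theta*d*(d-1)/2;
            # avoids catastrophic cancellation of gammaln at huge 1/theta
            return (P + theta * d * (d - 1) / 2.0
                    - np.log1p(theta * A) / theta - d * np.log1p(theta * A))
        inv = 1.0 / theta
        return (P + d * np.log(theta) + gammaln(inv + d) - gammaln(inv)
                - (inv + d) * np.log1p(theta * A))
    rule = rule or HermiteRule()
    x, w = rule.nodes, rule.weights
    z = np.sqrt(2.0 * theta) * x                     # (M,)
    expo = d[:, None] * z[None, :] - A[:, None] * np.exp(z)[None, :]
    return P + logsumexp(expo + np.log(w)[None, :], axis=1) - 0.5 * np.log(np.pi)


def cluster_loglik(time, event, arm, baselines: dict,
                   frailty: FrailtySpec, rule: HermiteRule | None = None) -> float:
    """Marginal log-likelihood of a single cluster.

    ``baselines`` maps arm (0/1) to a hazard object with ``log_hazard`` and
    ``cumulative_hazard``.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    arm = np.asarray(arm, dtype=int)
    if time.size == 0:
        raise ValueError("cluster must be nonempty")
    lnh = np.empty_like(time)
    H = np.empty_like(time)
    for a, hz in baselines.items():
        m = arm == a
        if m.any():
            lnh[m] = np.asarray(hz.log_hazard(time[m]), dtype=float)
            H[m] = np.asarray(hz.cumulative_hazard(time[m]), dtype=float)
    d = event.sum()
    A = H.sum()
    P = lnh[event == 1].sum()
    return float(_cluster_terms_loglik([d], [A], [P], frailty, rule)[0])


# ---------------------------------------------------------------------------
# Model


class SharedFrailtySurvivalModel:
    """Two-arm shared-frailty survival model for clustered data.

    Parameters
    ----------
    data : ClusteredSurvivalData
    baseline : str
        'weibull', 'pms', 'ptprs' or 'ncs'; one baseline per arm.
    frailty : str
        'gamma', 'lognormal' or 'none'.
    n_basis : int
        Spline basis size K per arm (splines only).
    fix_shape : bool
        Pin the Weibull shape at 1 (exponential baseline).
    hermite_nodes : int
        Gauss-Hermite nodes for log-normal marginalization.
    quad_points : int
        Gauss-Legendre nodes per subject for spline cumulative hazards.
    """

    def __init__(self, data: ClusteredSurvivalData, baseline: str = "weibull",
                 frailty: str = "gamma", n_basis: int = 6,
                 fix_shape: bool = False, hermite_nodes: int = 40,
                 quad_points: int = 24, bases: tuple | None = None):
        self.data = data
        self.baseline = baseline.lower()
        if self.baseline not in ("weibull",) + _SPLINE_FAMILIES:
            raise ValueError(f"unknown baseline family {baseline!r}")
        self.frailty_family = frailty.lower()
        if self.frailty_family not in ("gamma", "lognormal", "none"):
            raise ValueError(f"unknown frailty family {frailty!r}")
        self.n_basis = n_basis
        self.fix_shape = fix_shape
        self.rule = HermiteRule(hermite_nodes)
        self.quad = QuadratureGrid(quad_points)

        self.t = data.time
        self.d = data.event
        self.a = data.arm
        self.cl = data.cluster_codes
        self.n_clusters = data.n_clusters
        self._arm_idx = {arm: np.flatnonzero(self.a == arm) for arm in (0, 1)}
        self._logt = np.log(self.t)

        if self.baseline in _SPLINE_FAMILIES:
            if bases is not None:
                self.bases = bases
            else:
                self.bases = tuple(
                    build_spline_basis(
                        self.baseline,
                        self.t[(self.a == arm) & (self.d == 1)],
                        n_basis,
                    )
                    for arm in (0, 1)
                )
            self._Xt = {}
            self._Xn = {}
            self._Wn = {}
            for arm in (0, 1):
                idx = self._arm_idx[arm]
                basis = self.bases[arm]
                self._Xt[arm] = basis.matrix(self.t[idx])
                nodes, wts = self.quad.scaled(self.t[idx])
                self._Xn[arm] = basis.matrix(nodes.ravel())
                self._Wn[arm] = wts
        else:
            self.bases = None

        self.layout = self._build_layout()

    @classmethod
    def from_dataframe(cls, frame, **kwargs):
        return cls(ClusteredSurvivalData(frame), **kwargs)

    @classmethod
    def from_spec(cls, data: ClusteredSurvivalData, spec: ModelSpec, **kwargs):
        return cls(data, baseline=spec.baseline_family,
                   frailty=spec.frailty_family, n_basis=spec.n_basis,
                   fix_shape=spec.fix_shape, **kwargs)

    # -- parameter layout ---------------------------------------------------

    def _build_layout(self) -> list[str]:
        names = []
        for arm in (0, 1):
            if self.baseline == "weibull":
                names.append(f"arm{arm}.log_alpha")
                if not self.fix_shape:
                    names.append(f"arm{arm}.log_gamma")
            else:
                names.append(f"arm{arm}.intercept")
                names += [f"arm{arm}.b{k + 1}" for k in range(self.n_basis)]
        if self.frailty_family != "none":
            names.append("log_theta")
        return names

    @property
    def k_params(self) -> int:
        return len(self.layout)

    def _split_phi(self, phi):
        phi = np.asarray(phi, dtype=float)
        if phi.shape != (self.k_params,):
            raise ValueError(
                f"parameter vector has length {phi.size}, layout expects "
                f"{self.k_params}"
            )
        per_arm = (2 - self.fix_shape) if self.baseline == "weibull" \
            else self.n_basis + 1
        arm_params = [phi[i * per_arm:(i + 1) * per_arm] for i in (0, 1)]
        theta = np.exp(phi[-1]) if self.frailty_family != "none" else 0.0
        return arm_params, theta

    def hazards_from_phi(self, phi) -> dict:
        """Baseline hazard objects per arm implied by a parameter vector."""
        arm_params, _ = self._split_phi(phi)
        out = {}
        for arm in (0, 1):
            p = arm_params[arm]
            if self.baseline == "weibull":
                gamma = 1.0 if self.fix_shape else float(np.exp(p[1]))
                out[arm] = WeibullHazard(float(np.exp(p[0])), gamma)
            else:
                out[arm] = SplineLogHazard(self.bases[arm], float(p[0]), p[1:])
        return out

    def frailty_from_phi(self, phi) -> FrailtySpec:
        _, theta = self._split_phi(phi)
        return FrailtySpec(self.frailty_family, theta)

    # -- likelihood ---------------------------------------------------------

    def _subject_terms(self, phi, subjects=None):
        """Per-subject (ln h, H) for the requested subject indices."""
        arm_params, theta = self._split_phi(phi)
        n = self.t.size
        lnh = np.empty(n)
        H = np.empty(n)
        for arm in (0, 1):
            idx = self._arm_idx[arm]
            p = arm_params[arm]
            if self.baseline == "weibull":
                la = p[0]
                lg = 0.0 if self.fix_shape else p[1]
                gam = np.exp(lg)
                lnh[idx] = la + lg + (gam - 1.0) * self._logt[idx]
                H[idx] = np.exp(la) * self.t[idx] ** gam
            else:
                b0, beta = p[0], p[1:]
                lnh[idx] = b0 + self._Xt[arm] @ beta
                ln_nodes = b0 + self._Xn[arm] @ beta
                hn = np.exp(ln_nodes).reshape(self._Wn[arm].shape)
                H[idx] = np.sum(self._Wn[arm] * hn, axis=1)
        if subjects is not None:
            return lnh[subjects], H[subjects], theta
        return lnh, H, theta

    def loglike(self, phi, subjects=None) -> float:
        """Marginal (cluster-integrated) log-likelihood, unpenalized."""
        try:
            with np.errstate(over="raise", invalid="raise"):
                lnh, H, theta = self._subject_terms(phi, subjects)
        except FloatingPointError:
            return _BAD_LL
        cl = self.cl if subjects is None else self.cl[subjects]
        d = self.d if subjects is None else self.d[subjects]
        codes = cl if subjects is None else np.unique(cl, return_inverse=True)[1]
        ncl = codes.max() + 1
        d_j = np.bincount(codes, weights=d, minlength=ncl)
        A_j = np.bincount(codes, weights=H, minlength=ncl)
        P_j = np.bincount(codes, weights=d * lnh, minlength=ncl)
        fr = FrailtySpec(self.frailty_family, theta)
        ll = float(np.sum(_cluster_terms_loglik(d_j, A_j, P_j, fr, self.rule)))
        return ll if np.isfinite(ll) else _BAD_LL

    def penalized_loglike(self, phi, smoothing=0.0) -> float:
        """loglike minus (lambda_s / 2) * beta' S beta per arm (splines)."""
        ll = self.loglike(phi)
        if self.baseline in _SPLINE_FAMILIES and smoothing:
            arm_params, _ = self._split_phi(phi)
            for arm in (0, 1):
                beta = arm_params[arm][1:]
                ll -= 0.5 * smoothing * float(
                    beta @ self.bases[arm].penalty @ beta
                )
        return ll

    # -- fitting ------------------------------------------------------------

    def _start_values(self) -> np.ndarray:
        """Moment-based start: per-arm exponential rate, theta = 0.5."""
        start = []
        for arm in (0, 1):
            idx = self._arm_idx[arm]
            rate = max(self.d[idx].sum(), 0.5) / self.t[idx].sum()
            if self.baseline == "weibull":
                start.append(np.log(rate))
                if not self.fix_shape:
                    start.append(0.0)
            else:
                start += [np.log(rate)] + [0.0] * self.n_basis
        if self.frailty_family != "none":
            start.append(np.log(0.5))
        return np.array(start)

    def fit(self, smoothing: float | str | None = None, n_starts: int = 3,
            seed: int = 0, maxiter: int = 500,
            smoothing_grid=None) -> "SharedFrailtyResults":
        """Maximize the (penalized) marginal likelihood.

        ``smoothing``: fixed penalty weight, or 'cv' for cluster-level
        5-fold cross-validation over ``smoothing_grid`` (PMS/PTPRS only).
        Multi-start quasi-Newton: one moment-based start plus seeded
        jittered starts.
        """
        for arm in (0, 1):
            if self.d[self._arm_idx[arm]].sum() == 0:
                raise ValueError(
                    f"arm {arm} has zero events; the likelihood is "
                    "uninformative for its baseline"
                )
        penalized = self.baseline in ("pms", "ptprs")
        if smoothing is None:
            smoothing = "cv" if penalized else 0.0
        if smoothing == "cv":
            if penalized:
                smoothing = select_smoothing(
                    self.data, baseline=self.baseline,
                    frailty=self.frailty_family, n_basis=self.n_basis,
                    grid=smoothing_grid, seed=seed, bases=self.bases,
                )
            else:
                smoothing = 0.0
        lam = float(smoothing)

        def neg(phi):
            return -self.penalized_loglike(phi, lam)

        rng = np.random.default_rng(seed)
        base = self._start_values()
        starts = [base] + [base + rng.normal(0.0, 0.25, base.size)
                           for _ in range(max(0, n_starts - 1))]
        best = None
        for x0 in starts:
            res = optimize.minimize(neg, x0, method="L-BFGS-B",
                                    options={"maxiter": maxiter,
                                             "maxfun": 20 * maxiter})
            if best is None or res.fun < best.fun:
                best = res
        grad = approx_fprime(best.x, lambda p: self.penalized_loglike(p, lam),
                             centered=True)
        llpen = -best.fun
        grad_scaled = float(np.max(np.abs(grad))) / max(1.0, abs(llpen))
        convergence = {
            "status": int(best.status),
            "message": str(best.message),
            "iterations": int(best.nit),
            "grad_max": float(np.max(np.abs(grad))),
            "grad_max_scaled": grad_scaled,
            "n_starts": len(starts),
            "success": bool(best.success),
        }
        if not best.success and grad_scaled > 1e-3:
            raise ConvergenceError(
                f"optimizer did not converge: {best.message}",
                best_params=best.x, diagnostics=convergence,
            )

        hess = approx_hess3(best.x, lambda p: self.penalized_loglike(p, lam))
        neg_hess = -(hess + hess.T) / 2.0
        cov, repaired = _invert_with_repair(neg_hess)
        convergence["hessian_repaired"] = repaired
        if repaired:
            warnings.warn(
                "observed information not positive definite; nearest-PD "
                "repair applied to the covariance", UserWarning,
            )
        return SharedFrailtyResults(
            model=self,
            params=best.x,
            layout=list(self.layout),
            cov=cov,
            llf=float(self.loglike(best.x)),
            llf_penalized=float(llpen),
            smoothing={0: lam, 1: lam},
            convergence=convergence,
            baseline_family=self.baseline,
            frailty_family=self.frailty_family,
            fix_shape=self.fix_shape,
            n_basis=self.n_basis if self.bases else 0,
            bases=self.bases,
            hermite_nodes=self.rule.n_nodes,
        )


def _invert_with_repair(neg_hess, floor=1e-10):
    w, V = np.linalg.eigh(neg_hess)
    repaired = bool(np.any(w <= 0))
    w = np.clip(w, floor * max(1.0, float(np.max(np.abs(w)))), None)
    cov = (V / w) @ V.T
    return (cov + cov.T) / 2.0, repaired


def penalized_loglik(data: ClusteredSurvivalData, spec: ModelSpec, phi,
                     smoothing: float | None = None) -> float:
    """Functional form of the penalized log-likelihood for a ModelSpec."""
    model = SharedFrailtySurvivalModel.from_spec(data, spec)
    lam = smoothing if smoothing is not None else (
        spec.smoothing if isinstance(spec.smoothing, (int, float)) else 0.0
    )
    return model.penalized_loglike(phi, lam)


# ---------------------------------------------------------------------------
# Smoothing selection


DEFAULT_SMOOTHING_GRID = np.logspace(-4, 3, 10)


def select_smoothing(data: ClusteredSurvivalData, baseline: str,
                     frailty: str = "gamma", n_basis: int = 6,
                     grid=None, n_folds: int = 5, seed: int = 0,
                     n_starts: int = 1, bases=None) -> float:
    """Cluster-level K-fold cross-validated choice of the penalty weight.

    For each grid value, fit on the training clusters (penalized) and score
    the held-out clusters by their unpenalized marginal log-likelihood;
    return the grid argmax. Folds are built at cluster level to respect
    within-cluster dependence.
    """
    grid = DEFAULT_SMOOTHING_GRID if grid is None else np.asarray(grid, float)
    if grid.size == 1:
        return float(grid[0])
    if data.n_clusters < n_folds:
        raise ValueError(
            f"need at least {n_folds} clusters for {n_folds}-fold CV, "
            f"got {data.n_clusters}"
        )
    if bases is None:
        full = SharedFrailtySurvivalModel(data, baseline=baseline,
                                          frailty=frailty, n_basis=n_basis)
        bases = full.bases
    rng = np.random.default_rng(seed)
    ids = np.array(data.cluster_ids)
    perm = rng.permutation(len(ids))
    folds = [ids[perm[f::n_folds]] for f in range(n_folds)]
    scores = np.zeros(grid.size)
    for f, test_ids in enumerate(folds):
        train_ids = [c for c in ids if c not in set(test_ids)]
        train = SharedFrailtySurvivalModel(
            data.subset_clusters(train_ids), baseline=baseline,
            frailty=frailty, n_basis=n_basis, bases=bases,
        )
        test = SharedFrailtySurvivalModel(
            data.subset_clusters(test_ids), baseline=baseline,
            frailty=frailty, n_basis=n_basis, bases=bases,
        )
        for g, lam in enumerate(grid):
            fitted = train.fit(smoothing=float(lam), n_starts=n_starts,
                               seed=seed)
            scores[g] += test.loglike(fitted.params)
    return float(grid[int(np.argmax(scores))])


# ---------------------------------------------------------------------------
# Results


@dataclass
class SharedFrailtyResults:
    """Fitted shared-frailty model: phi-hat, covariance, diagnostics.

    Self-contained: it carries everything needed to evaluate marginal
    survival curves and the TTB (so a serialized results file can be used
    without the original data).
    """

    params: np.ndarray
    layout: list
    cov: np.ndarray
    llf: float
    llf_penalized: float
    smoothing: dict
    convergence: dict
    baseline_family: str
    frailty_family: str
    fix_shape: bool = False
    n_basis: int = 0
    bases: tuple | None = None
    hermite_nodes: int = 40
    model: SharedFrailtySurvivalModel | None = dc_field(default=None, repr=False)

    def __post_init__(self):
        self.params = np.asarray(self.params, dtype=float)
        self.cov = np.asarray(self.cov, dtype=float)

    # -- parameter access ---------------------------------------------------

    def cov_params(self) -> np.ndarray:
        return self.cov

    def bse(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.cov), 0.0, None))

    @property
    def theta(self) -> float:
        if self.frailty_family == "none":
            return 0.0
        return float(np.exp(self.params[-1]))

    def _split(self, phi):
        per_arm = (2 - self.fix_shape) if self.baseline_family == "weibull" \
            else self.n_basis + 1
        return [phi[i * per_arm:(i + 1) * per_arm] for i in (0, 1)]

    def hazards(self, phi=None) -> dict:
        phi = self.params if phi is None else np.asarray(phi, float)
        out = {}
        for arm, p in enumerate(self._split(phi)):
            if self.baseline_family == "weibull":
                gamma = 1.0 if self.fix_shape else float(np.exp(p[1]))
                out[arm] = WeibullHazard(float(np.exp(p[0])), gamma)
            else:
                out[arm] = SplineLogHazard(
                    self.bases[arm], float(p[0]), p[1:],
                    smoothing=self.smoothing.get(arm, 0.0),
                )
        return out

    def frailty(self, phi=None) -> FrailtySpec:
        phi = self.params if phi is None else np.asarray(phi, float)
        theta = np.exp(phi[-1]) if self.frailty_family != "none" else 0.0
        return FrailtySpec(self.frailty_family, float(theta))

    def curves(self, phi=None):
        """MarginalCurvePair for the fitted (or a supplied) parameter vector."""
        from .ttb import MarginalCurvePair
        return MarginalCurvePair(
            self.hazards(phi), self.frailty(phi),
            rule=HermiteRule(self.hermite_nodes),
        )

    def ttb(self, delta: float, method: str = "delta", t_max: float | None = None,
            tol: float = 1e-6, B: int = 1000, seed: int = 0):
        """Time-to-benefit estimate with a Delta-method or MC interval."""
        from . import ttb as _ttb
        req = _ttb.TTBRequest(delta_arr=delta, t_max=t_max, tol=tol)
        if method == "point":
            return _ttb.estimate_ttb(self.curves(),
                                     _ttb._resolve_t_max(self, req))
        if method == "delta":
            return _ttb.delta_ci(self, req)
        if method == "mc":
            return _ttb.mc_ci(self, req, B=B, seed=seed)
        raise ValueError(f"unknown method {method!r}")

    # -- reporting ----------------------------------------------------------

    def summary(self) -> str:
        lines = [
            "Shared-frailty survival model",
            f"  baseline: {self.baseline_family}   frailty: {self.frailty_family}",
            f"  log-likelihood: {self.llf:.4f}   "
            f"penalized: {self.llf_penalized:.4f}",
            f"  converged: {self.convergence.get('success')}   "
            f"iterations: {self.convergence.get('iterations')}",
            "",
            f"  {'parameter':<18}{'estimate':>12}{'std err':>12}"
            f"{'z':>10}{'P>|z|':>10}",
        ]
        from scipy.stats import norm
        se = self.bse()
        for name, est, s in zip(self.layout, self.params, se):
            z = est / s if s > 0 else np.nan
            p = 2 * norm.sf(abs(z)) if np.isfinite(z) else np.nan
            lines.append(f"  {name:<18}{est:>12.4f}{s:>12.4f}{z:>10.3f}{p:>10.4f}")
        if self.frailty_family != "none":
            i = self.layout.index("log_theta")
            th = self.theta
            se_th = th * se[i]          # delta method on exp(log_theta)
            z = self.params[i] / se[i] if se[i] > 0 else np.nan
            p = 2 * norm.sf(abs(z)) if np.isfinite(z) else np.nan
            lines.append("")
            lines.append(
                f"  frailty variance theta = {th:.4f} (SE {se_th:.4f}), "
                f"Wald test of ln theta: z = {z:.3f}, p = {p:.4g}"
            )
        return "\n".join(lines)

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        payload = {
            "params": self.params.tolist(),
            "layout": self.layout,
            "cov": self.cov.tolist(),
            "llf": self.llf,
            "llf_penalized": self.llf_penalized,
            "smoothing": {str(k): v for k, v in self.smoothing.items()},
            "convergence": self.convergence,
            "baseline_family": self.baseline_family,
            "frailty_family": self.frailty_family,
            "fix_shape": self.fix_shape,
            "n_basis": self.n_basis,
            "hermite_nodes": self.hermite_nodes,
            "bases": [b.to_dict() for b in self.bases] if self.bases else None,
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SharedFrailtyResults":
        d = json.loads(text)
        bases = None
        if d.get("bases"):
            bases = tuple(spline_basis_from_dict(b) for b in d["bases"])
        return cls(
            params=np.asarray(d["params"]),
            layout=list(d["layout"]),
            cov=np.asarray(d["cov"]),
            llf=d["llf"],
            llf_penalized=d["llf_penalized"],
            smoothing={int(k): v for k, v in d["smoothing"].items()},
            convergence=d["convergence"],
            baseline_family=d["baseline_family"],
            frailty_family=d["frailty_family"],
            fix_shape=d["fix_shape"],
            n_basis=d["n_basis"],
            bases=bases,
            hermite_nodes=d["hermite_nodes"],
        )
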