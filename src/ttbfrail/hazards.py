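"""Baseline hazard families: Weibull, piecewise Weibull, spline log-hazard.

All hazards expose ``hazard(t)`` and ``cumulative_hazard(t)`` (vectorized).
Weibull and piecewise Weibull use closed forms; spline log-hazards
(``ln h(t) = b0 + sum_k beta_k B_k(t)``) integrate the hazard numerically.

Three spline bases are provided: penalized M-splines (PMS, order-3 M-spline
basis with a second-order difference penalty), penalized thin-plate
regression splines (PTPRS, eigen-truncated |t - t_k|^3 radial basis with
the thin-plate wiggliness penalty, constraints absorbed mgcv-style), and
natural cubic splines (NCS, zero penalty). Because positivity of the hazard
comes from the exponential link, spline coefficients are unconstrained in
every family. Beyond the boundary knots the log-hazard is continued
linearly (for NCS this coincides with its natural linear tails).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import integrate
from scipy.interpolate import BSpline


class DegenerateDesignError(ValueError):
    """Too few distinct event times to build the requested spline basis."""


def _check_positive_time(t: np.ndarray, allow_zero: bool = False) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if allow_zero:
        if np.any(t < 0):
            raise ValueError("time must be nonnegative")
    elif np.any(t <= 0):
        raise ValueError("time must be strictly positive")
    return t


@dataclass(frozen=True)
class WeibullHazard:
    """Weibull baseline h(t) = alpha * gamma * t^(gamma-1), H(t) = alpha * t^gamma."""

    alpha: float
    gamma_shape: float

    def __post_init__(self):
        if self.alpha <= 0 or self.gamma_shape <= 0:
            raise ValueError("Weibull parameters must be positive")

    def hazard(self, t):
        t = _check_positive_time(t)
        return self.alpha * self.gamma_shape * t ** (self.gamma_shape - 1.0)

    def log_hazard(self, t):
        t = _check_positive_time(t)
        return (np.log(self.alpha) + np.log(self.gamma_shape)
                + (self.gamma_shape - 1.0) * np.log(t))

    def cumulative_hazard(self, t):
        t = _check_positive_time(t, allow_zero=True)
        return self.alpha * t ** self.gamma_shape

    def to_dict(self):
        return {"family": "weibull", "alpha": self.alpha,
                "gamma_shape": self.gamma_shape}


@dataclass(frozen=True)
class PiecewiseWeibullHazard:
    """Two Weibull regimes with a change point; H is continuous by construction.

    h(t) = lambda0*rho0*t^(rho0-1) for t <= t_change, else
    lambda1*rho1*t^(rho1-1). The cumulative hazard accumulates the pre-change
    mass so H is continuous and nondecreasing even when h jumps.
    """

    lambda0: float
    rho0: float
    lambda1: float
    rho1: float
    t_change: float = 1.0

    def __post_init__(self):
        if min(self.lambda0, self.rho0, self.lambda1, self.rho1,
               self.t_change) <= 0:
            raise ValueError("piecewise Weibull parameters must be positive")

    def hazard(self, t):
        t = _check_positive_time(t)
        pre = self.lambda0 * self.rho0 * t ** (self.rho0 - 1.0)
        post = self.lambda1 * self.rho1 * t ** (self.rho1 - 1.0)
        return np.where(t <= self.t_change, pre, post)

    def log_hazard(self, t):
        return np.log(self.hazard(t))

    def cumulative_hazard(self, t):
        t = _check_positive_time(t, allow_zero=True)
        tc = self.t_change
        h_pre_mass = self.lambda0 * tc ** self.rho0
        pre = self.lambda0 * np.minimum(t, tc) ** self.rho0
        post = self.lambda1 * (np.maximum(t, tc) ** self.rho1 - tc ** self.rho1)
        return np.where(t <= tc, pre, h_pre_mass + post)

    def to_dict(self):
        return {"family": "piecewise_weibull", "lambda0": self.lambda0,
                "rho0": self.rho0, "lambda1": self.lambda1, "rho1": self.rho1,
                "t_change": self.t_change}


# ---------------------------------------------------------------------------
# Spline bases


class SplineBasis:
    """A fixed spline basis on [t_lo, t_hi] with K functions and a penalty.

    ``matrix(t)`` returns the (len(t), K) design matrix; outside the
    boundary the basis is continued linearly from the nearest boundary.
    """

    def __init__(self, family: str, knots: np.ndarray, boundary: tuple,
                 penalty: np.ndarray, K: int):
        self.family = family
        self.knots = np.asarray(knots, dtype=float)
        self.boundary = (float(boundary[0]), float(boundary[1]))
        self.penalty = np.asarray(penalty, dtype=float)
        self.K = int(K)
        self._cache: dict[tuple, np.ndarray] = {}

    def _matrix_inside(self, t: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def matrix(self, t) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        lo, hi = self.boundary
        c = np.clip(t, lo, hi)
        X = self._matrix_inside(c)
        out = t != c
        if np.any(out):
            eps = 1e-6 * (hi - lo)
            cc = c[out]
            inward = np.where(cc > (lo + hi) / 2, cc - eps, cc + eps)
            dX = (self._matrix_inside(cc) - self._matrix_inside(inward)) / (
                cc - inward
            )[:, None]
            X[out] += (t[out] - cc)[:, None] * dX
        return X

    def matrix_cached(self, t: np.ndarray) -> np.ndarray:
        """``matrix`` memoized for large evaluation grids that repeat.

        Curve evaluation during Monte Carlo inference reuses the same time
        grid for every parameter draw; the design matrix depends only on
        the grid, so it is cached (keyed by size and endpoints).
        """
        if t.size < 256:
            return self.matrix(t)
        key = (t.size, float(t[0]), float(t[-1]))
        hit = self._cache.get(key)
        if hit is None:
            if len(self._cache) > 8:
                self._cache.clear()
            hit = self._cache[key] = self.matrix(t)
        return hit

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "knots": self.knots.tolist(),
            "boundary": list(self.boundary),
            "K": self.K,
        }


class MSplineBasis(SplineBasis):
    """Order-3 M-spline basis with a second-order difference penalty."""

    def __init__(self, interior, boundary, K):
        lo, hi = boundary
        tk = np.r_[[lo] * 3, interior, [hi] * 3]
        D2 = np.diff(np.eye(K), n=2, axis=0)
        super().__init__("pms", interior, boundary, D2.T @ D2, K)
        self._tk = tk
        # M_i = order * B_i / (t_{i+order} - t_i): integrates to 1, nonnegative
        self._norm = 3.0 / (tk[3:] - tk[:-3])

    def _matrix_inside(self, t):
        # clamp a hair inside so the rightmost B-spline is evaluated
        hi = self.boundary[1]
        tt = np.minimum(t, np.nextafter(hi, -np.inf))
        B = BSpline.design_matrix(tt, self._tk, 2).toarray()
        return B * self._norm


class ThinPlateBasis(SplineBasis):
    """Rank-reduced 1-D thin-plate basis: K-1 penalized columns + linear term.

    Radial functions |t - t*_j|^3 at m knot points are eigen-truncated to
    K+1 modes; the thin-plate constraints (orthogonality to the affine null
    space at the knots) are absorbed by a QR null-space rotation, leaving
    K-1 penalized functions. The linear null-space function is appended
    unpenalized; the constant merges with the model intercept.
    """

    def __init__(self, tstar, boundary, K):
        tstar = np.asarray(tstar, dtype=float)
        m = tstar.size
        E = np.abs(tstar[:, None] - tstar[None, :]) ** 3
        eigval, eigvec = np.linalg.eigh(E)
        order = np.argsort(np.abs(eigval))[::-1][: K + 1]
        U = eigvec[:, order]
        lam = eigval[order]
        T = np.column_stack([np.ones(m), tstar])
        C = U.T @ T                               # (K+1, 2) constraints
        Q, _ = np.linalg.qr(C, mode="complete")
        Z = Q[:, 2:]                              # (K+1, K-1)
        delta = U @ Z                             # (m, K-1) radial weights
        S_pen = Z.T @ np.diag(lam) @ Z
        S_pen = (S_pen + S_pen.T) / 2
        # rescale columns to unit RMS at the knots for optimizer conditioning
        # (f = X b is invariant: penalty transforms as S -> D S D, D = diag(c))
        raw = (np.abs(tstar[:, None] - tstar[None, :]) ** 3) @ delta
        col = np.sqrt(np.mean(raw ** 2, axis=0))
        col[col == 0] = 1.0
        delta = delta / col[None, :]
        S_pen = S_pen / (col[None, :] * col[:, None])
        w, V = np.linalg.eigh(S_pen)
        S_pen = V @ np.diag(np.clip(w, 0.0, None)) @ V.T   # PSD guarantee
        S = np.zeros((K, K))
        S[: K - 1, : K - 1] = S_pen
        super().__init__("ptprs", tstar, boundary, S, K)
        self._delta = delta
        self._tstar = tstar
        self._scale = boundary[1] - boundary[0]

    def _matrix_inside(self, t):
        R = np.abs(t[:, None] - self._tstar[None, :]) ** 3
        X = np.empty((t.size, self.K))
        X[:, : self.K - 1] = R @ self._delta
        X[:, self.K - 1] = (t - self.boundary[0]) / self._scale
        return X


class NaturalCubicBasis(SplineBasis):
    """Natural cubic spline basis (K non-constant functions over K+1 knots).

    Truncated-power construction with linear tails; the penalty matrix is
    identically zero (NCS is fitted unpenalized).
    """

    def __init__(self, knots, boundary, K):
        super().__init__("ncs", knots, boundary, np.zeros((K, K)), K)
        self._xi = np.asarray(knots, dtype=float)   # K+1 knots
        self._scale = boundary[1] - boundary[0]

    def _d(self, t, j):
        xi = self._xi
        last = xi[-1]
        return (np.maximum(t - xi[j], 0) ** 3 - np.maximum(t - last, 0) ** 3) / (
            last - xi[j]
        )

    def _matrix_inside(self, t):
        X = np.empty((t.size, self.K))
        X[:, 0] = (t - self.boundary[0]) / self._scale
        dlast = self._d(t, self.K - 1)
        for j in range(self.K - 1):
            X[:, j + 1] = (self._d(t, j) - dlast) / self._scale ** 3
        return X


def build_spline_basis(family: str, event_times, K: int = 6) -> SplineBasis:
    """Construct a spline basis from observed event times.

    Interior knots sit at event-time quantiles; the boundary spans the
    observed follow-up range. Requires K >= 3 and at least K distinct
    event times.
    """
    family = family.lower()
    if family not in ("pms", "ptprs", "ncs"):
        raise ValueError(f"unknown spline family {family!r}")
    if K < 3:
        raise ValueError("K must be at least 3")
    times = np.unique(np.asarray(event_times, dtype=float))
    if times.size < K:
        raise DegenerateDesignError(
            f"need at least {K} distinct event times, got {times.size}"
        )
    lo, hi = float(times.min()), float(times.max())
    if family == "pms":
        n_int = K - 3
        qs = np.linspace(0, 1, n_int + 2)[1:-1]
        interior = np.quantile(times, qs) if n_int else np.array([])
        return MSplineBasis(interior, (lo, hi), K)
    if family == "ptprs":
        m = min(times.size, max(20, K + 2))
        tstar = np.quantile(times, np.linspace(0, 1, m))
        tstar = np.unique(tstar)
        if tstar.size < K + 2:
            raise DegenerateDesignError(
                "too few distinct knot locations for the thin-plate basis"
            )
        return ThinPlateBasis(tstar, (lo, hi), K)
    knots = np.quantile(times, np.linspace(0, 1, K + 1))
    if np.unique(knots).size < K + 1:
        raise DegenerateDesignError("tied quantile knots for the NCS basis")
    return NaturalCubicBasis(knots, (lo, hi), K)


@dataclass
class SplineLogHazard:
    """Log-hazard spline model: ln h(t) = intercept + basis(t) @ coefficients."""

    basis: SplineBasis
    intercept: float
    coefficients: np.ndarray
    smoothing: float = 0.0

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.shape != (self.basis.K,):
            raise ValueError("coefficient length must equal basis size K")
        if self.smoothing < 0:
            raise ValueError("smoothing weight must be nonnegative")

    def log_hazard(self, t):
        t = _check_positive_time(t)
        return self.intercept + self.basis.matrix(t) @ self.coefficients

    def hazard(self, t):
        return np.exp(self.log_hazard(t))

    def cumulative_hazard(self, t):
        """Adaptive Gauss-Legendre (via QUADPACK) integral of the hazard."""
        t = np.atleast_1d(_check_positive_time(t, allow_zero=True))
        out = np.empty_like(t)
        for i, ti in enumerate(t):
            if ti == 0:
                out[i] = 0.0
            else:
                out[i], _ = integrate.quad(
                    lambda u: float(self.hazard(np.array([u]))[0]),
                    0.0, ti, epsrel=1e-10, epsabs=1e-12, limit=200,
                )
        return out if out.size > 1 else float(out[0])

    def penalty_value(self) -> float:
        b = self.coefficients
        return float(b @ self.basis.penalty @ b)

    def to_dict(self):
        d = self.basis.to_dict()
        d.update({
            "intercept": self.intercept,
            "coefficients": self.coefficients.tolist(),
            "smoothing": self.smoothing,
        })
        return d


@dataclass(frozen=True)
class QuadratureGrid:
    """Gauss-Legendre nodes/weights mapped from [-1, 1] to per-time panels."""

    n_points: int = 24
    nodes: np.ndarray = field(default=None, repr=False)
    weights: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        x, w = np.polynomial.legendre.leggauss(self.n_points)
        object.__setattr__(self, "nodes", x)
        object.__setattr__(self, "weights", w)

    def scaled(self, t):
        """Nodes/weights for integrating over [0, t] (t may be an array)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        half = t[:, None] / 2.0
        return half * (self.nodes[None, :] + 1.0), half * self.weights[None, :]


def spline_basis_from_dict(d: dict) -> SplineBasis:
    """Rebuild a basis from its ``to_dict`` payload (knots fully determine it)."""
    fam, knots, boundary, K = d["family"], np.asarray(d["knots"]), d["boundary"], d["K"]
    if fam == "pms":
        return MSplineBasis(knots, boundary, K)
    if fam == "ptprs":
        return ThinPlateBasis(knots, boundary, K)
    if fam == "ncs":
        return NaturalCubicBasis(knots, boundary, K)
    raise ValueError(f"unknown spline family {fam!r}")


def hazard_from_dict(d: dict):
    """Inverse of the ``to_dict`` serializers for closed-form hazards."""
    fam = d["family"]
    if fam == "weibull":
        return WeibullHazard(d["alpha"], d["gamma_shape"])
    if fam == "piecewise_weibull":
        return PiecewiseWeibullHazard(d["lambda0"], d["rho0"], d["lambda1"],
                                      d["rho1"], d["t_change"])
    if fam in ("pms", "ptprs", "ncs"):
        return SplineLogHazard(
            spline_basis_from_dict(d), d["intercept"],
            np.asarray(d["coefficients"]), d.get("smoothing", 0.0),
        )
    raise ValueError(f"cannot rebuild hazard family {fam!r}")
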