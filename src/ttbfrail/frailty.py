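"""Frailty distributions and marginalization of the conditional survival.

A shared frailty w multiplies the hazard of every subject in a cluster, so
the conditional survival given w is exp(-w * H(t)). The population-averaged
(marginal) survival is the frailty's Laplace transform evaluated at H(t):

* gamma frailty  w ~ Gamma(1/theta, 1/theta) (mean 1, variance theta):
  S(t) = (1 + theta * H(t))^(-1/theta), a closed form.
* log-normal frailty  ln w ~ N(0, theta): no closed form; the expectation
  is computed by Gauss-Hermite quadrature. The distribution is used exactly
  as stated (median 1, mean exp(theta/2) — no mean-one renormalization).
* none: w == 1, S(t) = exp(-H(t)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp


@dataclass(frozen=True)
class FrailtySpec:
    """Frailty family ('gamma' | 'lognormal' | 'none') and variance theta."""

    family: str = "gamma"
    theta: float = 0.0

    def __post_init__(self):
        if self.family not in ("gamma", "lognormal", "none"):
            raise ValueError(f"unknown frailty family {self.family!r}")
        if self.family != "none" and self.theta < 0:
            raise ValueError("frailty variance theta must be nonnegative")

    def to_dict(self):
        return {"family": self.family, "theta": self.theta}


@dataclass(frozen=True)
class HermiteRule:
    """Gauss-Hermite nodes/weights (physicists' convention, sum(w) = sqrt(pi))."""

    n_nodes: int = 40

    @property
    def nodes(self) -> np.ndarray:
        return _hermgauss_cached(self.n_nodes)[0]

    @property
    def weights(self) -> np.ndarray:
        return _hermgauss_cached(self.n_nodes)[1]


_HERM_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _hermgauss_cached(n: int) -> tuple[np.ndarray, np.ndarray]:
    if n not in _HERM_CACHE:
        _HERM_CACHE[n] = np.polynomial.hermite.hermgauss(n)
    return _HERM_CACHE[n]


def log_marginal_survival(H, frailty: FrailtySpec,
                          rule: HermiteRule | None = None):
    """ln S for cumulative hazard H >= 0 (vectorized; numerically stable)."""
    H = np.asarray(H, dtype=float)
    if np.any(H < 0):
        raise ValueError("cumulative hazard must be nonnegative")
    theta = frailty.theta
    if frailty.family == "none" or theta == 0.0:
        return -H
    if frailty.family == "gamma":
        # (1 + theta H)^(-1/theta) == exp(-log1p(theta H)/theta); log1p keeps
        # the theta -> 0 limit exp(-H) accurate for tiny theta.
        return -np.log1p(theta * H) / theta
    rule = rule or HermiteRule()
    x, w = rule.nodes, rule.weights
    z = np.sqrt(2.0 * theta) * x                    # ln w at nodes
    expo = -np.exp(z)[..., :] * H[..., None]        # (..., M)
    return logsumexp(expo + np.log(w), axis=-1) - 0.5 * np.log(np.pi)


def marginal_survival(H, frailty: FrailtySpec,
                      rule: HermiteRule | None = None):
    """Marginal survival S = E_w[exp(-w H)] in (0, 1]; S = 1 at H = 0."""
    return np.exp(log_marginal_survival(H, frailty, rule))


def frailty_sampler(frailty: FrailtySpec, n: int, seed=None) -> np.ndarray:
    """Draw n frailty values; reproducible under a fixed seed.

    Gamma draws have mean 1 and variance theta; log-normal draws have
    median 1. ``seed`` may be an int or a ``numpy.random.Generator``.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if frailty.family == "none" or frailty.theta == 0.0:
        return np.ones(n)
    if frailty.family == "gamma":
        k = 1.0 / frailty.theta
        return rng.gamma(shape=k, scale=frailty.theta, size=n)
    return np.exp(rng.normal(0.0, np.sqrt(frailty.theta), size=n))
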