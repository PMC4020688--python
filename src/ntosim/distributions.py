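"""Count and presence/absence distributions with overdispersion and zero-inflation.

Count families
--------------
All count families are parameterized by the marginal mean ``mu`` of the count
part and a dispersion parameter on the mean scale:

* ``poisson`` — variance ``mu``; no dispersion parameter.
* ``odpoisson`` — gamma mixing with variance proportional to the mean; marginal
  variance ``phi * mu`` with ``phi >= 1``.
* ``negbin`` — gamma mixing with variance ``omega * mu**2``; marginal variance
  ``mu + omega * mu**2``.
* ``poislognorm`` — lognormal mixing on the log scale; marginal variance
  ``mu + (exp(sigma2) - 1) * mu**2``, i.e. the negative-binomial variance
  function with ``omega = exp(sigma2) - 1``.

Presence/absence families
-------------------------
* ``binomial`` — mean ``n*pi``, variance ``n*pi*(1-pi)``.
* ``betabinom`` — beta mixing of the success probability; variance
  ``n*pi*(1-pi)*(1 + (n-1)*phi)`` with intraclass correlation ``phi``.
* ``binlogitnorm`` — normal random effect on the logit scale; moments have no
  closed form and are evaluated by Gauss–Hermite quadrature.

Zero inflation mixes any family with a structural-zero probability ``delta``:
``P(Y=0) = delta + (1-delta) * P_c(X=0)`` and
``P(Y=x) = (1-delta) * P_c(X=x)`` for ``x > 0``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from scipy.special import expit, logit

__all__ = [
    "CountDistributionSpec",
    "BinaryDistributionSpec",
    "native_params",
    "pmf",
    "sample",
    "zi_poisson_moments",
    "match_logitnormal",
    "moments",
]

COUNT_FAMILIES = ("poisson", "odpoisson", "negbin", "poislognorm")
BINARY_FAMILIES = ("binomial", "betabinom", "binlogitnorm")

#: default Gauss–Hermite order for integrating out lognormal random effects
GH_ORDER = 50


def _gh_nodes(order: int) -> tuple[np.ndarray, np.ndarray]:
    # nodes/weights for E[g(Z)], Z ~ N(0,1): sum w_i/sqrt(pi) * g(sqrt(2) x_i)
    x, w = np.polynomial.hermite.hermgauss(order)
    return np.sqrt(2.0) * x, w / np.sqrt(np.pi)


@dataclass(frozen=True)
class CountDistributionSpec:
    """One count distribution: family, marginal mean, dispersion, zero-inflation.

    ``dispersion`` is ``phi`` for ``odpoisson`` (>= 1), ``omega`` for
    ``negbin``, and for ``poislognorm`` either ``omega`` or ``sigma2``
    depending on ``dispersion_scale``.  ``delta`` in [0, 1) is the
    structural-zero probability; the marginal mean of the zero-inflated
    variable is ``(1 - delta) * mu``.
    """

    family: str
    mu: float
    dispersion: float | None = None
    delta: float = 0.0
    dispersion_scale: str = "omega"  # only relevant for poislognorm
    gh_order: int = GH_ORDER

    def __post_init__(self) -> None:
        if self.family not in COUNT_FAMILIES:
            raise ValueError(f"unknown count family {self.family!r}")
        if not self.mu > 0:
            raise ValueError("mu must be positive")
        if not 0.0 <= self.delta < 1.0:
            raise ValueError("delta must be in [0, 1)")
        if self.family == "poisson":
            if self.dispersion not in (None, 0.0):
                raise ValueError("poisson takes no dispersion parameter")
        else:
            if self.dispersion is None:
                raise ValueError(f"{self.family} requires a dispersion parameter")
            if self.family == "odpoisson" and self.dispersion < 1.0:
                raise ValueError("odpoisson dispersion phi must be >= 1")
            if self.family in ("negbin", "poislognorm") and self.dispersion < 0.0:
                raise ValueError("dispersion must be >= 0")
        if self.dispersion_scale not in ("omega", "sigma2"):
            raise ValueError("dispersion_scale must be 'omega' or 'sigma2'")

    @property
    def sigma2(self) -> float:
        """Lognormal mixing variance (poislognorm only), canonical scale."""
        if self.family != "poislognorm":
            raise AttributeError("sigma2 only defined for poislognorm")
        d = float(self.dispersion)
        return d if self.dispersion_scale == "sigma2" else float(np.log1p(d))

    @property
    def omega(self) -> float:
        """Quadratic overdispersion coefficient on the mean scale."""
        if self.family == "poislognorm":
            return float(np.expm1(self.sigma2))
        if self.family == "negbin":
            return float(self.dispersion)
        raise AttributeError("omega only defined for negbin/poislognorm")


@dataclass(frozen=True)
class BinaryDistributionSpec:
    """One presence/absence distribution for ``n`` plants per unit.

    ``dispersion`` is the intraclass correlation ``phi`` in [0, 1) for
    ``betabinom`` and the logit-normal variance ``sigma2`` for
    ``binlogitnorm``.  The logit-normal location defaults to ``logit(pi)``;
    use :func:`match_logitnormal` to find a location/variance pair with
    prescribed marginal moments.
    """

    family: str
    n: int
    pi: float
    dispersion: float | None = None
    delta: float = 0.0
    gh_order: int = GH_ORDER

    def __post_init__(self) -> None:
        if self.family not in BINARY_FAMILIES:
            raise ValueError(f"unknown binary family {self.family!r}")
        if not (isinstance(self.n, (int, np.integer)) and self.n >= 1):
            raise ValueError("n must be a positive integer")
        if not 0.0 < self.pi < 1.0:
            raise ValueError("pi must be in (0, 1)")
        if not 0.0 <= self.delta < 1.0:
            raise ValueError("delta must be in [0, 1)")
        if self.family == "binomial":
            if self.dispersion not in (None, 0.0):
                raise ValueError("binomial takes no dispersion parameter")
        else:
            if self.dispersion is None:
                raise ValueError(f"{self.family} requires a dispersion parameter")
            if self.family == "betabinom" and not 0.0 <= self.dispersion < 1.0:
                raise ValueError("betabinom phi must be in [0, 1)")
            if self.family == "binlogitnorm" and self.dispersion < 0.0:
                raise ValueError("binlogitnorm sigma2 must be >= 0")


def native_params(spec: CountDistributionSpec) -> dict:
    """Family-native parameters for direct sampling / pmf evaluation.

    * odpoisson: gamma mixing ``Z ~ Gamma(shape=mu/(phi-1), scale=phi-1)``
      (variance ``(phi-1)*mu``); degenerate at ``phi = 1``.
    * negbin: size ``k = 1/omega`` and success probability ``k/(k+mu)``.
    * poislognorm: lognormal location ``lam = log(mu) - sigma2/2`` so the
      marginal mean is exactly ``mu``.
    """
    if spec.family == "poisson":
        return {"family": "poisson", "mu": spec.mu}
    if spec.family == "odpoisson":
        phi = float(spec.dispersion)
        if phi == 1.0:
            return {"family": "odpoisson", "mu": spec.mu, "shape": np.inf, "scale": 0.0}
        return {
            "family": "odpoisson",
            "mu": spec.mu,
            "shape": spec.mu / (phi - 1.0),
            "scale": phi - 1.0,
        }
    if spec.family == "negbin":
        omega = float(spec.dispersion)
        if omega == 0.0:
            return {"family": "negbin", "mu": spec.mu, "size": np.inf, "prob": 1.0}
        k = 1.0 / omega
        return {"family": "negbin", "mu": spec.mu, "size": k, "prob": k / (k + spec.mu)}
    # poislognorm
    s2 = spec.sigma2
    return {
        "family": "poislognorm",
        "mu": spec.mu,
        "lam": float(np.log(spec.mu) - s2 / 2.0),
        "sigma2": s2,
    }


def _count_pmf_core(spec: CountDistributionSpec, x: np.ndarray) -> np.ndarray:
    """pmf of the count part (no zero-inflation)."""
    p = native_params(spec)
    if spec.family == "poisson":
        return stats.poisson.pmf(x, spec.mu)
    if spec.family == "odpoisson":
        phi = float(spec.dispersion)
        if phi == 1.0:
            return stats.poisson.pmf(x, spec.mu)
        # gamma-mixed Poisson with variance prop. to the mean is negative
        # binomial with size mu/(phi-1) and success prob 1/phi
        return stats.nbinom.pmf(x, p["shape"], 1.0 / phi)
    if spec.family == "negbin":
        if float(spec.dispersion) == 0.0:
            return stats.poisson.pmf(x, spec.mu)
        return stats.nbinom.pmf(x, p["size"], p["prob"])
    # poislognorm via Gauss–Hermite: E_Z[ Poisson pmf(x; exp(lam + sigma Z)) ]
    s2 = spec.sigma2
    if s2 == 0.0:
        return stats.poisson.pmf(x, spec.mu)
    nodes, weights = _gh_nodes(spec.gh_order)
    mus = np.exp(p["lam"] + np.sqrt(s2) * nodes)
    return stats.poisson.pmf(x[..., None], mus) @ weights


def _binary_pmf_core(spec: BinaryDistributionSpec, x: np.ndarray) -> np.ndarray:
    if spec.family == "binomial" or (
        spec.family == "betabinom" and float(spec.dispersion) == 0.0
    ):
        return stats.binom.pmf(x, spec.n, spec.pi)
    if spec.family == "betabinom":
        phi = float(spec.dispersion)
        a = spec.pi * (1.0 - phi) / phi
        b = (1.0 - spec.pi) * (1.0 - phi) / phi
        return stats.betabinom.pmf(x, spec.n, a, b)
    # binlogitnorm
    s2 = float(spec.dispersion)
    if s2 == 0.0:
        return stats.binom.pmf(x, spec.n, spec.pi)
    nodes, weights = _gh_nodes(spec.gh_order)
    probs = expit(logit(spec.pi) + np.sqrt(s2) * nodes)
    return stats.binom.pmf(x[..., None], spec.n, probs) @ weights


def pmf(
    spec: CountDistributionSpec | BinaryDistributionSpec,
    x: int | np.ndarray,
) -> float | np.ndarray:
    """P(Y = x) under the (possibly zero-inflated) distribution."""
    scalar = np.isscalar(x)
    xa = np.atleast_1d(np.asarray(x))
    if np.any(xa < 0):
        raise ValueError("x must be nonnegative")
    if isinstance(spec, BinaryDistributionSpec):
        if np.any(xa > spec.n):
            raise ValueError(f"x exceeds the number of plants n={spec.n}")
        core = _binary_pmf_core(spec, xa)
    else:
        core = _count_pmf_core(spec, xa)
    out = (1.0 - spec.delta) * core
    out = np.where(xa == 0, spec.delta + out, out)
    return float(out[0]) if scalar else out


def sample(
    spec: CountDistributionSpec | BinaryDistributionSpec,
    m: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw ``m`` i.i.d. observations.

    Zero inflation is applied as an independent Bernoulli(delta) structural
    zero mask on top of the count-part draws.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if isinstance(spec, BinaryDistributionSpec):
        if spec.family == "binomial" or float(spec.dispersion or 0.0) == 0.0:
            x = rng.binomial(spec.n, spec.pi, size=m)
        elif spec.family == "betabinom":
            phi = float(spec.dispersion)
            a = spec.pi * (1.0 - phi) / phi
            b = (1.0 - spec.pi) * (1.0 - phi) / phi
            x = rng.binomial(spec.n, rng.beta(a, b, size=m))
        else:
            p = expit(logit(spec.pi) + rng.normal(0.0, np.sqrt(spec.dispersion), m))
            x = rng.binomial(spec.n, p)
    else:
        x = _sample_count_part(
            spec.family, np.full(m, spec.mu), spec.dispersion, spec.dispersion_scale, rng
        )
    if spec.delta > 0.0:
        x = np.where(rng.random(m) < spec.delta, 0, x)
    return x


def _sample_count_part(
    family: str,
    mu: np.ndarray,
    dispersion: float | None,
    dispersion_scale: str,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorized count-part sampler for an array of unit means."""
    if family == "poisson":
        return rng.poisson(mu)
    if family == "odpoisson":
        phi = float(dispersion)
        if phi == 1.0:
            return rng.poisson(mu)
        z = rng.gamma(shape=mu / (phi - 1.0), scale=phi - 1.0)
        return rng.poisson(z)
    if family == "negbin":
        omega = float(dispersion)
        if omega == 0.0:
            return rng.poisson(mu)
        k = 1.0 / omega
        z = mu * rng.gamma(shape=k, scale=1.0 / k, size=mu.shape)
        return rng.poisson(z)
    if family == "poislognorm":
        s2 = dispersion if dispersion_scale == "sigma2" else float(np.log1p(dispersion))
        if s2 == 0.0:
            return rng.poisson(mu)
        lam = np.log(mu) - s2 / 2.0
        return rng.poisson(np.exp(lam + np.sqrt(s2) * rng.normal(size=mu.shape)))
    raise ValueError(f"unknown count family {family!r}")


def zi_poisson_moments(mu: float, delta: float) -> tuple[float, float]:
    """Mean and variance of the zero-inflated Poisson distribution.

    mean = mu*(1-delta), variance = mu*(1-delta)*(1+delta*mu).
    """
    if not mu > 0:
        raise ValueError("mu must be positive")
    if not 0.0 <= delta < 1.0:
        raise ValueError("delta must be in [0, 1)")
    return mu * (1.0 - delta), mu * (1.0 - delta) * (1.0 + delta * mu)


def moments(spec: CountDistributionSpec | BinaryDistributionSpec) -> tuple[float, float]:
    """Marginal mean and variance (count part only, i.e. delta = 0).

    Closed forms where they exist; Gauss–Hermite quadrature for the
    logit-normal family.
    """
    if isinstance(spec, CountDistributionSpec):
        if spec.family == "poisson":
            return spec.mu, spec.mu
        if spec.family == "odpoisson":
            return spec.mu, float(spec.dispersion) * spec.mu
        return spec.mu, spec.mu + spec.omega * spec.mu**2
    if spec.family == "binomial":
        return spec.n * spec.pi, spec.n * spec.pi * (1.0 - spec.pi)
    if spec.family == "betabinom":
        phi = float(spec.dispersion)
        v = spec.n * spec.pi * (1.0 - spec.pi) * (1.0 + (spec.n - 1) * phi)
        return spec.n * spec.pi, v
    return _logitnormal_binomial_moments(
        spec.n, logit(spec.pi), float(spec.dispersion), spec.gh_order
    )


def _logitnormal_binomial_moments(
    n: int, eta: float, sigma2: float, gh_order: int = GH_ORDER
) -> tuple[float, float]:
    """Quadrature mean/variance of X ~ Binomial(n, expit(eta + sigma*Z))."""
    if sigma2 == 0.0:
        p = expit(eta)
        return n * p, n * p * (1.0 - p)
    nodes, weights = _gh_nodes(gh_order)
    p = expit(eta + np.sqrt(sigma2) * nodes)
    ep = float(weights @ p)
    ep2 = float(weights @ (p * p))
    mean = n * ep
    # Var X = E[n p (1-p)] + n^2 Var(p)
    var = n * (ep - ep2) + n * n * (ep2 - ep * ep)
    return mean, var


def match_logitnormal(
    n: int, pi_target: float, omega_target: float, gh_order: int = GH_ORDER
) -> tuple[float, float]:
    """Find (eta, sigma2) so the binomial-logitnormal has prescribed moments.

    Solves for the logit-normal location ``eta`` and variance ``sigma2`` such
    that the marginal mean equals ``n * pi_target`` and the marginal variance
    equals ``omega_target * n * pi_target * (1 - pi_target)``, each to 1e-6
    relative tolerance.  ``omega_target = 1`` returns the plain binomial
    ``(logit(pi), 0)``.

    Raises ``RuntimeError`` with diagnostics when no solution is found (the
    target variance may be unattainable for extreme ``pi`` and ``omega``).
    """
    if not 0.0 < pi_target < 1.0:
        raise ValueError("pi_target must be in (0, 1)")
    if omega_target < 1.0:
        raise ValueError("omega_target must be >= 1 (binomial is omega = 1)")
    if omega_target == 1.0:
        return float(logit(pi_target)), 0.0

    mean_t = n * pi_target
    var_t = omega_target * n * pi_target * (1.0 - pi_target)

    def residual(params: np.ndarray) -> np.ndarray:
        eta, log_s2 = params
        m, v = _logitnormal_binomial_moments(n, eta, np.exp(log_s2), gh_order)
        return np.array([m / mean_t - 1.0, v / var_t - 1.0])

    # moment-based start: sigma2 from the extra variance of p, delta method
    extra = (var_t - n * pi_target * (1 - pi_target)) / (n * (n - 1))
    dp = pi_target * (1 - pi_target)
    s2_0 = max(extra / dp**2, 1e-4)
    sol = optimize.root(
        residual, x0=np.array([logit(pi_target), np.log(s2_0)]), method="hybr",
        options={"xtol": 1e-12},
    )
    if not sol.success or np.max(np.abs(sol.fun)) > 1e-6:
        raise RuntimeError(
            "moment matching for binomial-logitnormal failed: "
            f"n={n}, pi={pi_target}, omega={omega_target}, "
            f"residual={sol.fun}, message={sol.message}"
        )
    eta, log_s2 = sol.x
    return float(eta), float(np.exp(log_s2))
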