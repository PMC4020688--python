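"""Difference and equivalence testing for simulated trial datasets.

The analyses mirror what practitioners apply to single-trial NTO count data:

* maximum-likelihood fits of a negative binomial (or Poisson) model with one
  mean per variety and a common dispersion, under the null restriction
  mean(GM) = mean(comparator) or without it;
* the likelihood-ratio difference test with a chi-square(1) reference;
* a quasi-Poisson variant in which the Poisson likelihood-ratio statistic is
  scaled by the full-model mean deviance whenever that exceeds 1;
* a log-transform ANOVA (adding 0.5 before the log whenever the dataset
  contains a zero) with the GM-vs-comparator contrast t-test;
* a profile-likelihood confidence interval for the ratio of the GM and
  comparator means, used for TOST equivalence testing: non-equivalence is
  rejected when the interval lies completely inside the equivalence limits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import gammaln

__all__ = [
    "FitResult",
    "TestResult",
    "IntervalResult",
    "EquivalenceResult",
    "fit_count_model",
    "lrt_difference",
    "quasi_poisson_test",
    "loganova_test",
    "profile_ci_ratio",
    "tost_equivalence",
]

_MEAN_FLOOR = 1e-8
_LOG_OMEGA_BOUNDS = (-25.0, 12.0)
_OMEGA_POISSON_SWITCH = 1e-10


@dataclass
class FitResult:
    """ML fit of a one-mean-per-variety count model with common dispersion."""

    means: dict[str, float]  # response-scale mean per variety
    dispersion: float | None  # omega; None for the Poisson family
    loglik: float
    converged: bool
    constraint: str  # 'null' or 'full'
    family: str
    boundary: bool = False  # an all-zero variety was floored


@dataclass
class TestResult:
    statistic: float
    df: float
    p_value: float
    method: str


@dataclass
class IntervalResult:
    """Profile-likelihood CI for the GM/comparator mean ratio theta."""

    theta_hat: float
    lower: float
    upper: float
    level: float


@dataclass
class EquivalenceResult:
    interval: IntervalResult
    limits: tuple[float, float]
    equivalent: bool


# ---------------------------------------------------------------------------
# data extraction


def _groups(ds: pd.DataFrame) -> tuple[list[str], list[str], list[np.ndarray]]:
    """Per-variety response vectors plus their roles, GM and comparator first."""
    names, roles, xs = [], [], []
    for (name, role), sub in ds.groupby(["variety", "role"], sort=True):
        names.append(str(name))
        roles.append(str(role))
        xs.append(sub["response"].to_numpy(dtype=float))
    order = np.argsort([{"gm": 0, "comparator": 1}.get(r, 2) for r in roles], kind="stable")
    names = [names[i] for i in order]
    roles = [roles[i] for i in order]
    xs = [xs[i] for i in order]
    if roles[:2] != ["gm", "comparator"]:
        raise ValueError("dataset must contain exactly one gm and one comparator variety")
    return names, roles, xs


# ---------------------------------------------------------------------------
# likelihoods


def _poisson_loglik(xs: list[np.ndarray], means: np.ndarray) -> float:
    ll = 0.0
    for x, m in zip(xs, means):
        m = max(m, _MEAN_FLOOR)
        ll += float(np.sum(x) * np.log(m) - len(x) * m - np.sum(gammaln(x + 1.0)))
    return ll


def _negbin_loglik(xs: list[np.ndarray], means: np.ndarray, omega: float) -> float:
    """NB log-likelihood with size k = 1/omega and given group means."""
    k = 1.0 / omega
    ll = 0.0
    for x, m in zip(xs, means):
        m = max(m, _MEAN_FLOOR)
        n = len(x)
        ll += float(
            np.sum(gammaln(x + k)) - n * gammaln(k) - np.sum(gammaln(x + 1.0))
            + n * k * np.log(k / (k + m)) + np.sum(x) * np.log(m / (k + m))
        )
    return ll


def _group_means(xs: list[np.ndarray], constraint: str) -> tuple[np.ndarray, bool]:
    """ML group means: sample means, with GM/comparator pooled under the null.

    For both the Poisson and the negative binomial likelihood with fixed
    dispersion, the ML estimate of a free group mean is the sample mean, and
    of a pooled pair the pooled sample mean, so the dispersion profile only
    has to be maximized in one dimension.
    """
    means = np.array([x.mean() for x in xs])
    if constraint == "null":
        pooled = np.concatenate([xs[0], xs[1]]).mean()
        means[0] = means[1] = pooled
    boundary = bool(np.any(means < _MEAN_FLOOR))
    return np.maximum(means, _MEAN_FLOOR), boundary


def fit_count_model(
    ds: pd.DataFrame, family: str = "negbin", constraint: str = "full"
) -> FitResult:
    """Fit the one-mean-per-variety count model by maximum likelihood.

    ``constraint='null'`` restricts mean(GM) = mean(comparator) while any
    additional varieties keep free means; the dispersion is common to all
    varieties.  The negative-binomial dispersion is profiled on the log-omega
    scale with fixed bounds; an estimate at the lower boundary switches to the
    Poisson likelihood (the omega -> 0 limit).
    """
    if family not in ("negbin", "poisson"):
        raise ValueError("family must be 'negbin' or 'poisson'")
    if constraint not in ("null", "full"):
        raise ValueError("constraint must be 'null' or 'full'")
    names, _, xs = _groups(ds)
    if any(len(x) < 2 for x in xs):
        raise ValueError("each variety needs at least 2 observations")
    means, boundary = _group_means(xs, constraint)

    if family == "poisson":
        ll = _poisson_loglik(xs, means)
        return FitResult(dict(zip(names, means)), None, ll, True, constraint, family, boundary)

    res = optimize.minimize_scalar(
        lambda u: -_negbin_loglik(xs, means, np.exp(u)),
        bounds=_LOG_OMEGA_BOUNDS,
        method="bounded",
        options={"xatol": 1e-8},
    )
    omega = float(np.exp(res.x))
    ll = -float(res.fun)
    # boundary handling: the omega -> 0 limit is the Poisson likelihood; take
    # it whenever it does (essentially) as well as the interior optimum.  The
    # tolerance absorbs gammaln round-off at huge size parameters k = 1/omega.
    ll_pois = _poisson_loglik(xs, means)
    if omega < _OMEGA_POISSON_SWITCH or ll_pois >= ll - 1e-5:
        omega, ll = 0.0, max(ll, ll_pois)
    return FitResult(
        dict(zip(names, means)), omega, ll, bool(res.success), constraint, family, boundary
    )


# ---------------------------------------------------------------------------
# difference tests


def lrt_difference(ds: pd.DataFrame, family: str = "negbin") -> TestResult:
    """Likelihood-ratio test of H0: mean(GM) = mean(comparator).

    The statistic is twice the log-likelihood difference between the
    unrestricted and the restricted fit, referred to chi-square with 1 df.
    """
    full = fit_count_model(ds, family, "full")
    null = fit_count_model(ds, family, "null")
    stat = max(0.0, 2.0 * (full.loglik - null.loglik))
    p = float(stats.chi2.sf(stat, 1))
    return TestResult(stat, 1.0, p, f"{family}_lrt")


def quasi_poisson_test(ds: pd.DataFrame) -> TestResult:
    """Poisson LRT scaled by the full-model mean deviance when that exceeds 1."""
    names, _, xs = _groups(ds)
    means, _ = _group_means(xs, "full")
    null_means, _ = _group_means(xs, "null")
    lr = 2.0 * (_poisson_loglik(xs, means) - _poisson_loglik(xs, null_means))
    dev = 0.0
    n_total = 0
    for x, m in zip(xs, means):
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(x > 0, x * np.log(x / m), 0.0)
        dev += 2.0 * float(np.sum(term - (x - m)))
        n_total += len(x)
    mean_dev = dev / (n_total - len(xs))
    stat = max(0.0, lr / max(1.0, mean_dev))
    return TestResult(stat, 1.0, float(stats.chi2.sf(stat, 1)), "quasi_poisson_lrt")


def loganova_test(ds: pd.DataFrame) -> TestResult:
    """ANOVA of log counts; reported test is the GM-vs-comparator contrast.

    Counts are log transformed after adding 0.5 whenever the dataset contains
    at least one zero.  The contrast t statistic uses the residual variance
    pooled over all varieties.
    """
    _, _, xs = _groups(ds)
    shift = 0.5 if any((x == 0).any() for x in xs) else 0.0
    ys = [np.log(x + shift) for x in xs]
    n_total = sum(len(y) for y in ys)
    df = n_total - len(ys)
    if df < 2:
        raise ValueError("fewer than 2 residual degrees of freedom")
    sse = sum(float(np.sum((y - y.mean()) ** 2)) for y in ys)
    s2 = sse / df
    t = (ys[0].mean() - ys[1].mean()) / np.sqrt(s2 * (1.0 / len(ys[0]) + 1.0 / len(ys[1])))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return TestResult(float(t), float(df), p, "log_anova_contrast")


# ---------------------------------------------------------------------------
# profile-likelihood CI for the GM/comparator mean ratio


def _poisson_profile(xs: list[np.ndarray]):
    """Closed-form Poisson profile log-likelihood of theta (additional
    varieties contribute a constant and are dropped)."""
    x1, x2 = xs[0], xs[1]
    s1, s2 = float(x1.sum()), float(x2.sum())
    n1, n2 = len(x1), len(x2)

    def ll(log_theta: float) -> float:
        th = np.exp(log_theta)
        mu = (s1 + s2) / (n1 * th + n2)  # inner ML of the comparator mean
        mu = max(mu, _MEAN_FLOOR)
        return (
            s1 * (log_theta + np.log(mu)) - n1 * th * mu + s2 * np.log(mu) - n2 * mu
        )

    return ll


def _negbin_profile(xs: list[np.ndarray], start_mu: float, start_omega: float):
    """Numeric NB profile log-likelihood of theta, maximizing over the
    comparator mean and the common dispersion (additional-variety means stay
    at their sample means, which is their ML value for any dispersion)."""
    extra_means = [x.mean() for x in xs[2:]]
    state = {"x0": np.array([np.log(max(start_mu, _MEAN_FLOOR)),
                             np.log(max(start_omega, 1e-8))])}

    def ll(log_theta: float) -> float:
        def neg(params: np.ndarray) -> float:
            log_mu, u = params
            means = np.array(
                [np.exp(log_theta + log_mu), np.exp(log_mu)] + extra_means
            )
            return -_negbin_loglik(xs, np.maximum(means, _MEAN_FLOOR), np.exp(u))

        res = optimize.minimize(
            neg,
            x0=state["x0"],
            method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000},
        )
        state["x0"] = res.x  # warm start: successive thetas are close
        return -float(res.fun)

    return ll


def profile_ci_ratio(
    ds: pd.DataFrame, family: str = "poisson", level: float = 0.95
) -> IntervalResult:
    """Profile-likelihood CI for theta = mean(GM) / mean(comparator).

    The interval is {theta : 2 (l_hat - l_profile(theta)) <= chi2_1(level)},
    found by root bisection on the log-theta scale to 1e-6.
    """
    names, _, xs = _groups(ds)
    full = fit_count_model(ds, family, "full")
    mu_gm = full.means[names[0]]
    mu_c = full.means[names[1]]
    theta_hat = mu_gm / mu_c
    crit = float(stats.chi2.ppf(level, 1))

    if family == "poisson":
        prof = _poisson_profile(xs)
    else:
        prof = _negbin_profile(xs, mu_c, full.dispersion or 0.25)

    lt_hat = float(np.log(theta_hat))
    ll_hat = prof(lt_hat)

    def g(lt: float) -> float:
        return 2.0 * (ll_hat - prof(lt)) - crit

    def find_root(direction: float) -> float:
        step = 0.25
        lo = lt_hat
        for _ in range(200):
            hi = lo + direction * step
            if g(hi) > 0:
                a, b = sorted((lo, hi))
                return float(optimize.brentq(g, a, b, xtol=1e-6))
            lo = hi
            step *= 1.5
        raise RuntimeError("profile CI endpoint search did not converge")

    lower = float(np.exp(find_root(-1.0)))
    upper = float(np.exp(find_root(+1.0)))
    return IntervalResult(float(theta_hat), lower, upper, level)


def tost_equivalence(
    ci: IntervalResult, limits: tuple[float, float]
) -> EquivalenceResult:
    """Reject non-equivalence when the CI lies wholly inside the limits.

    A single (1 - alpha) interval inside (L, U) operationalizes the two
    one-sided tests at level alpha/2 each.
    """
    L, U = limits
    if not 0 < L < U:
        raise ValueError("equivalence limits must satisfy 0 < L < U")
    equivalent = bool(L < ci.lower and ci.upper < U)
    return EquivalenceResult(ci, (float(L), float(U)), equivalent)


def results_frame(results: list) -> pd.DataFrame:
    """Serialize mixed test/interval/equivalence results to one flat table."""
    rows = []
    for r in results:
        row = dict.fromkeys(
            ["method", "statistic", "df", "p", "theta_hat", "lower", "upper", "equivalent"],
            None,
        )
        if isinstance(r, TestResult):
            row.update(method=r.method, statistic=r.statistic, df=r.df, p=r.p_value)
        elif isinstance(r, IntervalResult):
            row.update(
                method="profile_ci", theta_hat=r.theta_hat, lower=r.lower, upper=r.upper
            )
        elif isinstance(r, EquivalenceResult):
            row.update(
                method="tost", theta_hat=r.interval.theta_hat, lower=r.interval.lower,
                upper=r.interval.upper, equivalent=r.equivalent,
            )
        else:
            raise TypeError(f"cannot serialize {type(r).__name__}")
        rows.append(row)
    return pd.DataFrame(rows)
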