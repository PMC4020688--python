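"""Monte-Carlo power analysis over replication grids.

For each replication level N on a grid, many datasets are simulated and an
analysis (difference test or TOST equivalence) is applied; the rejection
fraction estimates the power.  The replication needed to reach a target power
(default 0.80) is interpolated linearly in N after isotonic smoothing of the
raw curve, with censored rendering ("≤4", "≥40") outside the grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression

from . import engine, inference
from .model import (
    DesignSpec,
    FamilySpec,
    ScenarioConfig,
    TimeCoefficients,
    TimeSpec,
    VarietySpec,
)

__all__ = [
    "Analysis",
    "PowerCurve",
    "RequiredN",
    "TableResult",
    "estimate_power",
    "required_replications",
    "reproduce_table",
    "crd_count_config",
    "repeated_measures_config",
    "DEFAULT_N_GRID",
]

#: replication grid used throughout the worked power studies
DEFAULT_N_GRID = (4, 6, 8, 10, 15, 20, 30, 40)

ANALYSIS_TAGS = ("negbin_lrt", "poisson_lrt", "quasi_poisson", "log_anova", "equivalence")


@dataclass(frozen=True)
class Analysis:
    """What to do with one simulated dataset.

    ``tag`` picks the procedure; ``equivalence`` computes a profile-likelihood
    CI for the GM/comparator mean ratio (family ``ci_family``) at confidence
    ``level`` and "rejects" when the CI lies inside ``limits``.
    ``aggregate_time`` sums repeated measurements per unit before analysis.
    """

    tag: str
    limits: tuple[float, float] | None = None
    level: float = 0.95
    ci_family: str = "poisson"
    aggregate_time: bool = False

    def __post_init__(self) -> None:
        if self.tag not in ANALYSIS_TAGS:
            raise ValueError(f"unknown analysis {self.tag!r}; choose from {ANALYSIS_TAGS}")
        if self.tag == "equivalence" and self.limits is None:
            raise ValueError("equivalence analysis requires limits (L, U)")

    def rejects(self, ds: pd.DataFrame, alpha: float) -> bool:
        if self.aggregate_time:
            ds = engine.aggregate_time(ds)
        if self.tag == "negbin_lrt":
            return inference.lrt_difference(ds, "negbin").p_value < alpha
        if self.tag == "poisson_lrt":
            return inference.lrt_difference(ds, "poisson").p_value < alpha
        if self.tag == "quasi_poisson":
            return inference.quasi_poisson_test(ds).p_value < alpha
        if self.tag == "log_anova":
            return inference.loganova_test(ds).p_value < alpha
        ci = inference.profile_ci_ratio(ds, self.ci_family, self.level)
        return inference.tost_equivalence(ci, self.limits).equivalent


@dataclass
class PowerCurve:
    """Rejection fraction per replication level with Monte-Carlo SEs."""

    n_grid: tuple[int, ...]
    power: np.ndarray
    se: np.ndarray
    n_sims: int
    alpha: float
    analysis: str
    failures: np.ndarray  # analysis failures per N, excluded from denominators


@dataclass(frozen=True)
class RequiredN:
    """Interpolated replication needed for the target power.

    ``censored`` is None for an interior value, 'at_most_min' when the power
    already exceeds the target at the smallest grid N, 'at_least_max' when it
    stays below the target at the largest.
    """

    value: int
    target: float
    censored: str | None = None

    def render(self) -> str:
        if self.censored == "at_most_min":
            return f"≤{self.value}"
        if self.censored == "at_least_max":
            return f"≥{self.value}"
        return str(self.value)


def estimate_power(
    config_factory: Callable[[int], ScenarioConfig],
    analysis: Analysis,
    n_grid: tuple[int, ...] = DEFAULT_N_GRID,
    n_sims: int = 1000,
    alpha: float = 0.05,
    seed: "int | np.random.SeedSequence" = 0,
    common_random: bool = False,
) -> PowerCurve:
    """Monte-Carlo rejection fraction for each replication level.

    ``config_factory(N)`` must return the scenario with N replicates.  Fresh
    random-number substreams are used for every N unless ``common_random``;
    analysis failures are excluded from the denominator and counted.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    ss = engine._seed_sequence(seed)
    children = ss.spawn(len(n_grid))
    power = np.empty(len(n_grid))
    se = np.empty(len(n_grid))
    failures = np.zeros(len(n_grid), dtype=int)
    for i, n_rep in enumerate(n_grid):
        config = config_factory(int(n_rep))
        if common_random:
            # a fresh SeedSequence with identical keys replays the same
            # stream at every N (spawning mutates the parent's counter)
            child = np.random.SeedSequence(
                entropy=children[0].entropy, spawn_key=children[0].spawn_key
            )
        else:
            child = children[i]
        rejections = 0
        n_ok = 0
        for ds in engine.simulate_batch(config, n_sims, child, include_truth=False):
            try:
                rejections += analysis.rejects(ds, alpha)
                n_ok += 1
            except (RuntimeError, ValueError):
                failures[i] += 1
        p = rejections / n_ok if n_ok else np.nan
        power[i] = p
        se[i] = math.sqrt(p * (1.0 - p) / n_ok) if n_ok else np.nan
    return PowerCurve(
        tuple(int(n) for n in n_grid), power, se, n_sims, alpha, analysis.tag, failures
    )


def required_replications(curve: PowerCurve, target: float = 0.80) -> RequiredN:
    """Smallest replication reaching the target power.

    The raw curve is first made monotone by isotonic regression (Monte-Carlo
    noise can produce small violations), then the target crossing is found by
    linear interpolation in N and rounded up to an integer.  Curves entirely
    above (below) the target are censored at the grid minimum (maximum).
    """
    grid = np.asarray(curve.n_grid, dtype=float)
    p = IsotonicRegression(increasing=True).fit_transform(grid, curve.power)
    if p[0] >= target:
        return RequiredN(int(grid[0]), target, "at_most_min")
    if p[-1] < target:
        return RequiredN(int(grid[-1]), target, "at_least_max")
    i = int(np.argmax(p >= target)) - 1
    if p[i + 1] == p[i]:
        n_star = grid[i + 1]
    else:
        n_star = grid[i] + (target - p[i]) / (p[i + 1] - p[i]) * (grid[i + 1] - grid[i])
    return RequiredN(int(math.ceil(n_star - 1e-9)), target, None)


# ---------------------------------------------------------------------------
# scenario builders for the standard single-trial studies


def crd_count_config(
    family: str,
    mu_comparator: float,
    theta: float,
    n_replicates: int,
    dispersion: float | None = None,
    delta: float = 0.0,
    n_additional: int = 1,
) -> ScenarioConfig:
    """Completely randomized single-trial count scenario.

    The comparator and ``n_additional`` additional varieties share the
    count-part mean ``mu_comparator``; the GM plant has mean
    ``theta * mu_comparator``.  With ``delta`` > 0 every variety gets the same
    structural-zero probability, so the marginal means are
    ``(1 - delta) * mu``.
    """
    from scipy.special import logit

    zero = float(logit(delta)) if delta > 0 else None
    varieties = [
        VarietySpec("gm", "gm", float(np.log(theta * mu_comparator)), zero),
        VarietySpec("comparator", "comparator", float(np.log(mu_comparator)), zero),
    ]
    for i in range(1, n_additional + 1):
        varieties.append(
            VarietySpec(f"additional{i}", "additional", float(np.log(mu_comparator)), zero)
        )
    return ScenarioConfig(
        family=FamilySpec(family, dispersion),
        varieties=tuple(varieties),
        design=DesignSpec("crd", n_replicates),
    )


def repeated_measures_config(
    mu_max: float,
    theta: float,
    n_replicates: int,
    mode: str,
    omega: float = 0.25,
    beta_opt: float = 0.0,
    beta_tol: float = 47.96,
    rho: float = 0.8,
    n_additional: int = 1,
) -> ScenarioConfig:
    """Quadratic-in-time Poisson count scenario with lognormal random effects.

    The comparator (and additional varieties) peak at mean ``mu_max`` at time
    0 and the GM plant at ``theta * mu_max``; observations sit at days
    -14, -7, 0, 7, 14.  The random effects v_t on the log scale have variance
    ``sigma2 = log(1 + omega)``, making each single observation marginally
    Poisson-lognormal with dispersion omega.  ``mode``:

    * ``single`` — one observation per unit at day 0;
    * ``independent`` — five uncorrelated v_t per unit (equal corr., rho 0);
    * ``dependent`` — five AR1-correlated v_t with correlation ``rho``.
    """
    sigma2 = float(np.log1p(omega))
    if mode == "single":
        time = TimeSpec(1, "quadratic", "equal", 0.0, sigma2, labels=(0.0,))
    elif mode == "independent":
        time = TimeSpec(5, "quadratic", "equal", 0.0, sigma2, labels=(-14, -7, 0, 7, 14))
    elif mode == "dependent":
        time = TimeSpec(5, "quadratic", "ar1", rho, sigma2, labels=(-14, -7, 0, 7, 14))
    else:
        raise ValueError("mode must be single, independent or dependent")

    def coeffs(peak: float) -> TimeCoefficients:
        return TimeCoefficients(
            beta_max=float(np.log(peak)), beta_opt=beta_opt, beta_tol=beta_tol
        )

    varieties = [
        VarietySpec("gm", "gm", time_coefficients=coeffs(theta * mu_max)),
        VarietySpec("comparator", "comparator", time_coefficients=coeffs(mu_max)),
    ]
    for i in range(1, n_additional + 1):
        varieties.append(
            VarietySpec(f"additional{i}", "additional", time_coefficients=coeffs(mu_max))
        )
    return ScenarioConfig(
        family=FamilySpec("poisson"),
        varieties=tuple(varieties),
        design=DesignSpec("crd", n_replicates),
        time=time,
    )


# ---------------------------------------------------------------------------
# table reproductions


@dataclass
class TableResult:
    """A required-replication table plus its per-cell power curves."""

    table_id: str
    rendered: pd.DataFrame  # strings as printed ("9", "<=4", ">=40", "-")
    required: dict[tuple, RequiredN]
    curves: dict[tuple, PowerCurve]

    def to_csv(self, path) -> None:
        self.rendered.to_csv(path)

    def se_frame(self) -> pd.DataFrame:
        """Monte-Carlo SE of the power at each grid N, one row per cell."""
        rows = []
        for key, curve in self.curves.items():
            for n, p, se in zip(curve.n_grid, curve.power, curve.se):
                rows.append({"cell": str(key), "N": n, "power": p, "se": se})
        return pd.DataFrame(rows)


MU_VALUES = (1, 2, 5, 10, 20, 40)
THETA_VALUES = (1.0, 1.2, 1.4, 1.6, 1.8, 2.0)
OMEGA_VALUES = (0.25, 0.50, 1.00)


def reproduce_table(
    table_id: str,
    n_sims: int = 1000,
    seed: "int | np.random.SeedSequence" = 0,
    n_grid: tuple[int, ...] = DEFAULT_N_GRID,
    alpha: float = 0.05,
    target: float = 0.80,
    mu_values: tuple[float, ...] | None = None,
    row_values: tuple[float, ...] | None = None,
) -> TableResult:
    """Required-replication sweeps for the three worked studies.

    * ``T3`` — negative-binomial difference test, theta = 2, rows are the
      dispersion omega in {0.25, 0.5, 1}, columns the comparator mean mu.
    * ``T4`` — Poisson data; a difference-test block and a TOST-equivalence
      block with limits (1/2, 2), rows are theta.  The degenerate rows
      (theta = 1 for difference, theta = 2 on the equivalence limit) are
      rendered as "-".
    * ``T5`` — repeated-measures Poisson-lognormal scenario (omega = 0.25,
      quadratic time with beta_tol = 47.96, AR1 rho = 0.8); TOST equivalence
      with limits (1/3, 3) from a negative-binomial profile CI on the summed
      counts; columns single / dependent / independent sampling.

    ``mu_values`` / ``row_values`` restrict the sweep (useful for spot
    checks); the full T5 sweep is expensive and is meant for explicit runs.
    """
    ss = engine._seed_sequence(seed)
    mus = tuple(mu_values if mu_values is not None else MU_VALUES)
    required: dict[tuple, RequiredN] = {}
    curves: dict[tuple, PowerCurve] = {}

    def run_cell(key, factory, analysis, child) -> None:
        curve = estimate_power(factory, analysis, n_grid, n_sims, alpha, child)
        curves[key] = curve
        required[key] = required_replications(curve, target)

    if table_id == "T3":
        omegas = tuple(row_values if row_values is not None else OMEGA_VALUES)
        children = iter(ss.spawn(len(omegas) * len(mus)))
        analysis = Analysis("negbin_lrt")
        for om in omegas:
            for mu in mus:
                run_cell(
                    (om, mu),
                    lambda N, mu=mu, om=om: crd_count_config("negbin", mu, 2.0, N, om),
                    analysis,
                    next(children),
                )
        rendered = _render(required, omegas, mus, "omega")
    elif table_id == "T4":
        thetas = tuple(row_values if row_values is not None else THETA_VALUES)
        children = iter(ss.spawn(2 * len(thetas) * len(mus)))
        eq = Analysis("equivalence", limits=(0.5, 2.0), ci_family="poisson")
        for block, analysis in (("difference", Analysis("poisson_lrt")), ("equivalence", eq)):
            for th in thetas:
                for mu in mus:
                    key = (block, th, mu)
                    degenerate = (block == "difference" and th == 1.0) or (
                        block == "equivalence" and th >= 2.0
                    )
                    child = next(children)
                    if degenerate:
                        continue
                    run_cell(
                        key,
                        lambda N, mu=mu, th=th: crd_count_config("poisson", mu, th, N),
                        analysis,
                        child,
                    )
        rows = []
        for block in ("difference", "equivalence"):
            for th in thetas:
                row = {"block": block, "theta": th}
                for mu in mus:
                    r = required.get((block, th, mu))
                    row[f"mu={mu:g}"] = r.render() if r is not None else "-"
                rows.append(row)
        rendered = pd.DataFrame(rows).set_index(["block", "theta"])
    elif table_id == "T5":
        modes = ("single", "dependent", "independent")
        children = iter(ss.spawn(len(mus) * len(modes)))
        analysis = Analysis(
            "equivalence", limits=(1.0 / 3.0, 3.0), ci_family="negbin", aggregate_time=True
        )
        for mu in mus:
            for mode in modes:
                run_cell(
                    (mu, mode),
                    lambda N, mu=mu, mode=mode: repeated_measures_config(mu, 2.0, N, mode),
                    analysis,
                    next(children),
                )
        rows = []
        for mu in mus:
            row = {"mu_max": mu}
            for mode in modes:
                row[mode] = required[(mu, mode)].render()
            rows.append(row)
        rendered = pd.DataFrame(rows).set_index("mu_max")
    else:
        raise ValueError("table_id must be 'T3', 'T4' or 'T5'")
    return TableResult(table_id, rendered, required, curves)


def _render(required, rows, mus, row_name) -> pd.DataFrame:
    out = []
    for r in rows:
        row = {row_name: r}
        for mu in mus:
            row[f"mu={mu:g}"] = required[(r, mu)].render()
        out.append(row)
    return pd.DataFrame(out).set_index(row_name)
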