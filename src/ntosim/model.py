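"""Scenario description and linear-predictor assembly.

A field trial scenario consists of a GM plant, its conventional comparator,
optional additional varieties (fixed effects) and optional reference-variety
populations (random effects), laid out in a completely randomized (CRD) or
randomized complete block (RCB) design, possibly replicated over multiple
trials or a site-by-year grid, possibly with repeated measurements in time.

All effects live on the transformed scale: natural log for count means and
logit for probabilities (success probability of presence/absence data and the
structural-zero probability ``delta``).  The unit-level mean is
``mu = exp(eta_count)`` and the unit-level structural-zero probability is
``delta = expit(eta_zero)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .distributions import BINARY_FAMILIES, COUNT_FAMILIES

__all__ = [
    "Normal",
    "VarietySpec",
    "DesignSpec",
    "TrialStructure",
    "TimeSpec",
    "TimeCoefficients",
    "FamilySpec",
    "ScenarioConfig",
    "EffectDraw",
    "quad_coefficients",
    "correlation_matrix",
    "draw_effects",
    "linear_predictor",
]

ROLES = ("gm", "comparator", "additional", "reference_population")


@dataclass(frozen=True)
class Normal:
    """A normal law N(mean, variance) used to specify random effects."""

    mean: float
    variance: float

    def __post_init__(self) -> None:
        if self.variance < 0:
            raise ValueError("variance must be >= 0")


EffectLike = "float | Normal"


def _as_effect(x) -> "float | Normal":
    if isinstance(x, Normal):
        return x
    if isinstance(x, (tuple, list)) and len(x) == 2:
        return Normal(float(x[0]), float(x[1]))
    if isinstance(x, dict):
        return Normal(float(x["mean"]), float(x["variance"]))
    return float(x)


@dataclass(frozen=True)
class TimeCoefficients:
    """Per-variety time-pattern coefficients on the transformed scale.

    For ``constant`` supply ``beta0``; for ``linear`` also ``beta1``; for
    ``quadratic`` either the polynomial triple (``beta0``, ``beta1``,
    ``beta2``) or the peak form (``beta_max``, ``beta_opt``, ``beta_tol``)
    where the extreme value ``beta_max`` is attained at time ``beta_opt`` and
    ``beta_tol`` controls the width of the parabola (positive: maximum,
    negative: minimum).  Each entry may be a float or a :class:`Normal`
    (reference populations draw every coefficient from its normal law).
    """

    beta0: "float | Normal | None" = None
    beta1: "float | Normal | None" = None
    beta2: "float | Normal | None" = None
    beta_max: "float | Normal | None" = None
    beta_opt: "float | Normal | None" = None
    beta_tol: "float | Normal | None" = None

    def is_peak_form(self) -> bool:
        return self.beta_max is not None


@dataclass(frozen=True)
class VarietySpec:
    """One variety (or treatment) entry in the scenario.

    ``count_effect`` is the variety effect for the count/presence part on the
    log (or logit) scale; ``zero_effect`` the structural-zero effect on the
    logit scale.  Both are fixed numbers for gm/comparator/additional
    varieties and :class:`Normal` laws for a ``reference_population``, which
    stands for ``n_reference`` exchangeable varieties with a history of safe
    use.
    """

    name: str
    role: str
    count_effect: "float | Normal | None" = None
    zero_effect: "float | Normal | None" = None
    n_reference: int | None = None
    time_coefficients: TimeCoefficients | None = None
    zero_time_coefficients: TimeCoefficients | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown variety role {self.role!r}")
        object.__setattr__(self, "count_effect", _maybe_effect(self.count_effect))
        object.__setattr__(self, "zero_effect", _maybe_effect(self.zero_effect))
        if self.role == "reference_population":
            if self.n_reference is None or self.n_reference < 1:
                raise ValueError("reference_population requires n_reference >= 1")
            if self.count_effect is not None and not isinstance(self.count_effect, Normal):
                raise ValueError("reference_population count_effect must be (mean, variance)")
        elif self.n_reference is not None:
            raise ValueError("n_reference only valid for reference_population")


def _maybe_effect(x):
    return None if x is None else _as_effect(x)


@dataclass(frozen=True)
class DesignSpec:
    """Experimental layout within one trial.

    CRD is simulated as RCB with zero block variance and blocks relabeled as
    plots, which unifies the code path.
    """

    layout: str
    n_replicates: int
    block_variance_count: float = 0.0
    block_variance_zero: float = 0.0

    def __post_init__(self) -> None:
        if self.layout not in ("crd", "rcb"):
            raise ValueError("layout must be 'crd' or 'rcb'")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.block_variance_count < 0 or self.block_variance_zero < 0:
            raise ValueError("block variances must be >= 0")
        if self.layout == "crd" and (
            self.block_variance_count > 0 or self.block_variance_zero > 0
        ):
            raise ValueError("crd has no blocks; block variances must be 0")


@dataclass(frozen=True)
class TrialStructure:
    """Multi-environment structure: none, unstructured trials, or site x year.

    ``gxe_variance`` switches on genotype-by-environment interaction: the
    variety effect in each trial is drawn from a normal law centred at the
    variety's main effect, so GM-vs-comparator differences keep a common basis
    across trials.  Reference populations use a two-stage scheme per trial: a
    trial-level reference mean M ~ N(m, s1^2), then per-variety effects
    ~ N(M, s2^2).
    """

    kind: str = "single"
    n_trials: int = 1
    n_sites: int | None = None
    n_years: int | None = None
    trial_variance: float = 0.0
    site_variance: float = 0.0
    year_variance: float = 0.0
    site_year_variance: float = 0.0
    gxe_variance: float | None = None
    reference_between_trial_variance: float | None = None  # s1^2
    reference_within_trial_variance: float | None = None  # s2^2

    def __post_init__(self) -> None:
        if self.kind not in ("single", "multiple", "site_by_year"):
            raise ValueError("kind must be single, multiple or site_by_year")
        if self.kind == "single":
            if self.n_trials != 1:
                raise ValueError("single trial structure has n_trials = 1")
            for v in (self.trial_variance, self.site_variance, self.year_variance,
                      self.site_year_variance):
                if v not in (0, 0.0):
                    raise ValueError("single-trial scenario cannot have trial-level variances")
        if self.kind == "site_by_year":
            if not (self.n_sites and self.n_years):
                raise ValueError("site_by_year requires n_sites and n_years")
            object.__setattr__(self, "n_trials", self.n_sites * self.n_years)
        if self.kind == "multiple" and self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")

    def trial_index(self) -> list[tuple[int | None, int | None]]:
        """(site, year) labels per trial; (None, None) when unstructured."""
        if self.kind == "site_by_year":
            return [(s, y) for s in range(self.n_sites) for y in range(self.n_years)]
        return [(None, None)] * self.n_trials


@dataclass(frozen=True)
class TimeSpec:
    """Repeated-measurement structure.

    Time points are integers 1..T internally; ``labels`` maps them affinely
    onto a user scale (e.g. -14..14 days) and the time coefficients are
    interpreted on that scale.  ``correlation`` chooses the law of the extra
    random effects v_t on the transformed scale: ``independent`` means no
    extra variability (v = 0), ``equal`` a compound-symmetry correlation rho,
    ``ar1`` an autoregressive correlation rho^|k-l|.  Note that ``equal`` or
    ``ar1`` with ``random_variance`` > 0 is an overdispersion mechanism: with
    rho = 0 under a Poisson family it reproduces the Poisson-lognormal law.
    """

    n_timepoints: int
    pattern: str = "constant"
    correlation: str = "independent"
    rho: float = 0.0
    random_variance: float = 0.0
    labels: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_timepoints < 1:
            raise ValueError("n_timepoints must be >= 1")
        if self.pattern not in ("constant", "linear", "quadratic"):
            raise ValueError("pattern must be constant, linear or quadratic")
        if self.correlation not in ("independent", "equal", "ar1"):
            raise ValueError("correlation must be independent, equal or ar1")
        if self.random_variance < 0:
            raise ValueError("random_variance must be >= 0")
        if self.labels is None:
            object.__setattr__(
                self, "labels", tuple(float(t) for t in range(1, self.n_timepoints + 1))
            )
        else:
            object.__setattr__(self, "labels", tuple(float(t) for t in self.labels))
            if len(self.labels) != self.n_timepoints:
                raise ValueError("labels must have length n_timepoints")
        # rho validity is checked in correlation_matrix (needs T)


@dataclass(frozen=True)
class FamilySpec:
    """Distribution family shared by all varieties: family + common dispersion.

    The per-unit mean (or success probability) comes from the linear
    predictor; the dispersion parameter is common to all varieties and trials.
    """

    family: str
    dispersion: float | None = None
    dispersion_scale: str = "omega"
    n: int | None = None  # binomial index for presence/absence families

    def __post_init__(self) -> None:
        if self.family not in COUNT_FAMILIES + BINARY_FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.is_binary and (self.n is None or self.n < 1):
            raise ValueError("binary families require a positive n")
        if self.family == "odpoisson" and (self.dispersion is None or self.dispersion < 1):
            raise ValueError("odpoisson requires dispersion phi >= 1")
        if self.family in ("negbin", "poislognorm", "betabinom", "binlogitnorm"):
            if self.dispersion is None or self.dispersion < 0:
                raise ValueError(f"{self.family} requires a nonnegative dispersion")

    @property
    def is_binary(self) -> bool:
        return self.family in BINARY_FAMILIES


@dataclass(frozen=True)
class ScenarioConfig:
    """Full description of one simulation scenario."""

    family: FamilySpec
    varieties: tuple[VarietySpec, ...]
    design: DesignSpec
    trials: TrialStructure = TrialStructure()
    time: TimeSpec | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "varieties", tuple(self.varieties))
        roles = [v.role for v in self.varieties]
        if roles.count("gm") != 1 or roles.count("comparator") != 1:
            raise ValueError("scenario requires exactly one gm and one comparator variety")
        names = [v.name for v in self.varieties]
        if len(set(names)) != len(names):
            raise ValueError("variety names must be unique")
        if self.time is None:
            for v in self.varieties:
                if v.role != "reference_population" and not isinstance(v.count_effect, float):
                    raise ValueError(
                        f"variety {v.name!r} needs a fixed count_effect in a scenario without time"
                    )
        else:
            for v in self.varieties:
                if v.time_coefficients is None:
                    raise ValueError(
                        f"variety {v.name!r} needs time_coefficients when time is specified"
                    )
        if self.has_zero_model:
            for v in self.varieties:
                if v.zero_effect is None and v.zero_time_coefficients is None:
                    raise ValueError(
                        f"variety {v.name!r} lacks a zero_effect while others define one"
                    )

    @property
    def has_zero_model(self) -> bool:
        return any(
            v.zero_effect is not None or v.zero_time_coefficients is not None
            for v in self.varieties
        )

    def expanded_varieties(self) -> list[tuple[str, str, VarietySpec]]:
        """(name, role, spec) with reference populations unrolled to members."""
        out: list[tuple[str, str, VarietySpec]] = []
        for v in self.varieties:
            if v.role == "reference_population":
                for i in range(1, v.n_reference + 1):
                    out.append((f"{v.name}{i}", "reference", v))
            else:
                out.append((v.name, v.role, v))
        return out


@dataclass
class EffectDraw:
    """One realization of every random effect in a scenario.

    Arrays are indexed by (trial, block, variety, time) position; ``varieties``
    records the expanded variety names defining the variety axis.  Fixed
    effects are folded in: ``variety_count[i, j]`` is the realized total
    variety effect of variety j in trial i (fixed effect, reference draw
    and genotype-by-environment draw combined).
    """

    varieties: list[str]
    block_count: np.ndarray  # (n_trials, n_blocks)
    block_zero: np.ndarray
    env_count: np.ndarray  # (n_trials,) trial/site/year/site-x-year sum
    env_zero: np.ndarray
    variety_count: np.ndarray  # (n_trials, n_varieties)
    variety_zero: np.ndarray
    time_poly_count: np.ndarray | None = None  # (n_trials, n_varieties, 3)
    time_poly_zero: np.ndarray | None = None
    v: np.ndarray | None = None  # (n_trials, n_blocks, n_varieties, T)


def quad_coefficients(beta_max: float, beta_opt: float, beta_tol: float) -> tuple[float, float, float]:
    """Convert the peak parameterization of a quadratic time pattern to
    polynomial coefficients.

    ``f(t) = beta_max - (t - beta_opt)^2 / (2 beta_tol)
           = beta0 + beta1 t + beta2 t^2``
    with ``beta2 = -1/(2 beta_tol)``, ``beta1 = beta_opt/beta_tol`` and
    ``beta0 = beta_max - beta_opt^2/(2 beta_tol)``.
    """
    if beta_tol == 0:
        raise ValueError("beta_tol must be nonzero")
    b2 = -1.0 / (2.0 * beta_tol)
    b1 = beta_opt / beta_tol
    b0 = beta_max - beta_opt**2 / (2.0 * beta_tol)
    return b0, b1, b2


def correlation_matrix(time: TimeSpec) -> np.ndarray:
    """T x T correlation matrix V of the time random effects.

    ``independent`` returns the identity (the associated random effects are
    identically zero); ``equal`` sets V_kl = rho off the diagonal; ``ar1``
    sets V_kl = rho^|k-l|.  Non-positive-semi-definite choices are rejected.
    """
    T = time.n_timepoints
    if time.correlation == "independent":
        return np.eye(T)
    rho = time.rho
    if not -1.0 < rho <= 1.0:
        raise ValueError("rho must be in (-1, 1]")
    if time.correlation == "equal":
        if T > 1 and rho < -1.0 / (T - 1):
            raise ValueError(f"equal correlation rho={rho} is not PSD for T={T}")
        V = np.full((T, T), rho)
        np.fill_diagonal(V, 1.0)
        return V
    if abs(rho) >= 1.0 and T > 1:
        raise ValueError("ar1 requires |rho| < 1")
    k = np.arange(T)
    return rho ** np.abs(k[:, None] - k[None, :])


def _draw(rng: np.random.Generator, eff, size=None) -> np.ndarray | float:
    """Realize a float-or-Normal effect specification."""
    if isinstance(eff, Normal):
        return rng.normal(eff.mean, np.sqrt(eff.variance), size=size)
    return eff if size is None else np.full(size, float(eff))


def _resolve_poly(
    coeffs: TimeCoefficients, pattern: str, rng: np.random.Generator
) -> tuple[float, float, float]:
    """Realize one variety's time polynomial (drawing any Normal entries)."""
    if coeffs.is_peak_form():
        if pattern != "quadratic":
            raise ValueError("peak-form coefficients require the quadratic pattern")
        bm = _draw(rng, coeffs.beta_max)
        bo = _draw(rng, coeffs.beta_opt if coeffs.beta_opt is not None else 0.0)
        bt = _draw(rng, coeffs.beta_tol)
        return quad_coefficients(float(bm), float(bo), float(bt))
    b0 = float(_draw(rng, coeffs.beta0 if coeffs.beta0 is not None else 0.0))
    b1 = b2 = 0.0
    if pattern in ("linear", "quadratic") and coeffs.beta1 is not None:
        b1 = float(_draw(rng, coeffs.beta1))
    if pattern == "quadratic" and coeffs.beta2 is not None:
        b2 = float(_draw(rng, coeffs.beta2))
    return b0, b1, b2


def draw_effects(config: ScenarioConfig, rng: np.random.Generator) -> EffectDraw:
    """Draw one realization of all random effects of the scenario.

    Count-part and zero-part effects are drawn independently.  Varieties are
    processed in sorted-name order so that permuting the variety list in the
    configuration leaves the simulated joint law invariant.
    """
    tr = config.trials
    n_trials = tr.n_trials
    n_blocks = config.design.n_replicates
    expanded = config.expanded_varieties()
    names = [n for n, _, _ in expanded]
    n_var = len(names)

    sb_c = np.sqrt(config.design.block_variance_count)
    sb_z = np.sqrt(config.design.block_variance_zero)
    block_count = rng.normal(0.0, 1.0, (n_trials, n_blocks)) * sb_c
    block_zero = rng.normal(0.0, 1.0, (n_trials, n_blocks)) * sb_z

    env_count = np.zeros(n_trials)
    env_zero = np.zeros(n_trials)
    if tr.kind == "multiple":
        env_count += rng.normal(0.0, 1.0, n_trials) * np.sqrt(tr.trial_variance)
        env_zero += rng.normal(0.0, 1.0, n_trials) * np.sqrt(tr.trial_variance)
    elif tr.kind == "site_by_year":
        site = rng.normal(0.0, 1.0, tr.n_sites) * np.sqrt(tr.site_variance)
        year = rng.normal(0.0, 1.0, tr.n_years) * np.sqrt(tr.year_variance)
        sy = rng.normal(0.0, 1.0, (tr.n_sites, tr.n_years)) * np.sqrt(tr.site_year_variance)
        env_count += np.array(
            [site[s] + year[y] + sy[s, y] for s, y in tr.trial_index()]
        )

    variety_count = np.zeros((n_trials, n_var))
    variety_zero = np.zeros((n_trials, n_var))
    order = sorted(range(n_var), key=lambda j: names[j])
    # trial-level reference means M, shared by all members of one population
    ref_means: dict[tuple[str, str], np.ndarray] = {}

    def pop_mean(spec: VarietySpec, part: str, eff: Normal) -> np.ndarray:
        key = (spec.name, part)
        if key not in ref_means:
            s1 = tr.reference_between_trial_variance
            if s1 is None or n_trials == 1:
                s1 = 0.0
            ref_means[key] = rng.normal(eff.mean, np.sqrt(s1), n_trials)
        return ref_means[key]

    for j in order:
        _, role, spec = expanded[j]
        variety_count[:, j] = _realized_effects(
            spec.count_effect, role, tr, rng, n_trials,
            pop_mean(spec, "count", spec.count_effect) if role == "reference" else None,
        )
        if spec.zero_effect is not None:
            variety_zero[:, j] = _realized_effects(
                spec.zero_effect, role, tr, rng, n_trials,
                pop_mean(spec, "zero", spec.zero_effect) if role == "reference" else None,
            )

    time_poly_count = time_poly_zero = v = None
    if config.time is not None:
        ts = config.time
        T = ts.n_timepoints
        time_poly_count = np.zeros((n_trials, n_var, 3))
        time_poly_zero = np.zeros((n_trials, n_var, 3))
        for j in order:
            _, role, spec = expanded[j]
            for i in range(n_trials):
                same_draw = role != "reference" and i > 0 and tr.gxe_variance is None
                if same_draw:
                    time_poly_count[i, j] = time_poly_count[0, j]
                    time_poly_zero[i, j] = time_poly_zero[0, j]
                    continue
                time_poly_count[i, j] = _resolve_poly(spec.time_coefficients, ts.pattern, rng)
                if tr.gxe_variance is not None and role != "reference":
                    time_poly_count[i, j, 0] += rng.normal(0.0, np.sqrt(tr.gxe_variance))
                if spec.zero_time_coefficients is not None:
                    time_poly_zero[i, j] = _resolve_poly(
                        spec.zero_time_coefficients, ts.pattern, rng
                    )
                elif spec.zero_effect is not None:
                    time_poly_zero[i, j, 0] = variety_zero[i, j]
        if ts.correlation != "independent" and ts.random_variance > 0:
            V = correlation_matrix(ts)
            L = np.linalg.cholesky(V + 1e-12 * np.eye(T))
            z = rng.normal(0.0, 1.0, (n_trials, n_blocks, n_var, T))
            v = np.sqrt(ts.random_variance) * (z @ L.T)
        else:
            v = np.zeros((n_trials, n_blocks, n_var, T))

    return EffectDraw(
        varieties=names,
        block_count=block_count,
        block_zero=block_zero,
        env_count=env_count,
        env_zero=env_zero,
        variety_count=variety_count,
        variety_zero=variety_zero,
        time_poly_count=time_poly_count,
        time_poly_zero=time_poly_zero,
        v=v,
    )


def _realized_effects(
    eff, role: str, tr: TrialStructure, rng: np.random.Generator, n_trials: int,
    pop_mean: np.ndarray | None = None,
) -> np.ndarray:
    """Per-trial realized variety effect: fixed, reference draw, or G-by-E."""
    if eff is None:  # time model carries the level via the coefficients
        return np.zeros(n_trials)
    if role == "reference":
        assert isinstance(eff, Normal)
        # two-stage: trial-level reference mean M (shared within the
        # population, drawn by the caller), then this variety around M
        s2 = tr.reference_within_trial_variance
        if s2 is None:
            s2 = eff.variance
        return rng.normal(pop_mean, np.sqrt(s2))
    base = float(eff) if not isinstance(eff, Normal) else eff.mean
    if tr.gxe_variance is not None:
        return rng.normal(base, np.sqrt(tr.gxe_variance), n_trials)
    return np.full(n_trials, base)


def linear_predictor(
    config: ScenarioConfig,
    draw: EffectDraw,
    trial: np.ndarray | int,
    block: np.ndarray | int,
    variety: np.ndarray | int,
    timepoint: np.ndarray | int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Assemble (eta_count, eta_zero) for units keyed by integer indices.

    ``variety`` indexes ``draw.varieties``; ``timepoint`` indexes the time
    axis (0-based).  The count-part predictor is the realized variety effect
    plus block and environment effects plus, under a time model, the time
    polynomial f_p(t) evaluated at the user-scale time label and the random
    effect v_t.  The unit mean is ``exp(eta_count)`` and the structural-zero
    probability ``expit(eta_zero)``.
    """
    trial = np.asarray(trial, dtype=int)
    block = np.asarray(block, dtype=int)
    variety = np.asarray(variety, dtype=int)
    timepoint = np.asarray(timepoint, dtype=int)
    trial, block, variety, timepoint = np.broadcast_arrays(trial, block, variety, timepoint)

    eta_c = draw.env_count[trial] + draw.block_count[trial, block]
    eta_z = draw.env_zero[trial] + draw.block_zero[trial, block]
    if config.time is None:
        eta_c = eta_c + draw.variety_count[trial, variety]
        eta_z = eta_z + draw.variety_zero[trial, variety]
    else:
        t = np.asarray(config.time.labels)[timepoint]
        pc = draw.time_poly_count[trial, variety]  # (..., 3)
        eta_c = eta_c + pc[..., 0] + pc[..., 1] * t + pc[..., 2] * t**2
        eta_c = eta_c + draw.v[trial, block, variety, timepoint]
        pz = draw.time_poly_zero[trial, variety]
        eta_z = eta_z + pz[..., 0] + pz[..., 1] * t + pz[..., 2] * t**2
    return eta_c, eta_z
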