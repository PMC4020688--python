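"""Read and write scenario configurations as TOML text.

Schema (sections map one-to-one onto the scenario dataclasses)::

    [distribution]
    family = "negbin"            # poisson|odpoisson|negbin|poislognorm|
                                 # binomial|betabinom|binlogitnorm
    dispersion = 0.25
    dispersion_scale = "omega"   # or "sigma2" (poislognorm only)
    # n = 16                     # binary families only

    [design]
    layout = "rcb"               # crd|rcb
    replicates = 20
    block_variance_count = 0.1
    block_variance_zero = 0.01

    [[variety]]
    name = "gm"
    role = "gm"                  # gm|comparator|additional|reference_population
    count_effect = 0.4           # or {mean = 1.0, variance = 1.0}
    zero_effect = -0.3
    # n_reference = 3            # reference_population only
    # [variety.time_coefficients]
    # beta_max = 0.69
    # beta_opt = 0.0
    # beta_tol = 47.96

    [trials]
    kind = "single"              # single|multiple|site_by_year
    # n_trials, n_sites, n_years, trial_variance, site_variance,
    # year_variance, site_year_variance, gxe_variance,
    # reference_between_trial_variance, reference_within_trial_variance

    [time]                       # optional
    n_timepoints = 5
    pattern = "quadratic"        # constant|linear|quadratic
    correlation = "ar1"          # independent|equal|ar1
    rho = 0.8
    random_variance = 0.223
    labels = [-14, -7, 0, 7, 14]
"""

from __future__ import annotations

import tomllib
from dataclasses import asdict

from .model import (
    DesignSpec,
    FamilySpec,
    Normal,
    ScenarioConfig,
    TimeCoefficients,
    TimeSpec,
    TrialStructure,
    VarietySpec,
)

__all__ = ["load_config", "parse_config", "dump_config"]


class ConfigError(ValueError):
    """A scenario file failed validation; the message names the field."""


def load_config(path) -> ScenarioConfig:
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    return parse_config(data)


def _effect(value):
    if isinstance(value, dict):
        try:
            return Normal(float(value["mean"]), float(value["variance"]))
        except KeyError as exc:
            raise ConfigError(f"effect table needs 'mean' and 'variance': {value}") from exc
    return float(value)


def _coefficients(table: dict) -> TimeCoefficients:
    known = {"beta0", "beta1", "beta2", "beta_max", "beta_opt", "beta_tol"}
    unknown = set(table) - known
    if unknown:
        raise ConfigError(f"unknown time coefficient field(s) {sorted(unknown)}")
    return TimeCoefficients(**{k: _effect(v) for k, v in table.items()})


def parse_config(data: dict) -> ScenarioConfig:
    """Build a validated ScenarioConfig from parsed TOML data."""
    for section in ("distribution", "design", "variety"):
        if section not in data:
            raise ConfigError(f"missing required section [{section}]")
    d = data["distribution"]
    try:
        family = FamilySpec(
            family=d["family"],
            dispersion=d.get("dispersion"),
            dispersion_scale=d.get("dispersion_scale", "omega"),
            n=d.get("n"),
        )
    except (KeyError, ValueError) as exc:
        raise ConfigError(f"[distribution]: {exc}") from exc

    g = data["design"]
    try:
        design = DesignSpec(
            layout=g.get("layout", "crd"),
            n_replicates=int(g["replicates"]),
            block_variance_count=float(g.get("block_variance_count", 0.0)),
            block_variance_zero=float(g.get("block_variance_zero", 0.0)),
        )
    except (KeyError, ValueError) as exc:
        raise ConfigError(f"[design]: {exc}") from exc

    varieties = []
    for i, v in enumerate(data["variety"]):
        try:
            varieties.append(
                VarietySpec(
                    name=v.get("name", f"variety{i + 1}"),
                    role=v["role"],
                    count_effect=_effect(v["count_effect"]) if "count_effect" in v else None,
                    zero_effect=_effect(v["zero_effect"]) if "zero_effect" in v else None,
                    n_reference=v.get("n_reference"),
                    time_coefficients=(
                        _coefficients(v["time_coefficients"])
                        if "time_coefficients" in v else None
                    ),
                    zero_time_coefficients=(
                        _coefficients(v["zero_time_coefficients"])
                        if "zero_time_coefficients" in v else None
                    ),
                )
            )
        except (KeyError, ValueError) as exc:
            raise ConfigError(f"[[variety]] entry {i + 1}: {exc}") from exc

    t = data.get("trials", {})
    try:
        trials = TrialStructure(
            kind=t.get("kind", "single"),
            n_trials=int(t.get("n_trials", 1)),
            n_sites=t.get("n_sites"),
            n_years=t.get("n_years"),
            trial_variance=float(t.get("trial_variance", 0.0)),
            site_variance=float(t.get("site_variance", 0.0)),
            year_variance=float(t.get("year_variance", 0.0)),
            site_year_variance=float(t.get("site_year_variance", 0.0)),
            gxe_variance=t.get("gxe_variance"),
            reference_between_trial_variance=t.get("reference_between_trial_variance"),
            reference_within_trial_variance=t.get("reference_within_trial_variance"),
        )
    except ValueError as exc:
        raise ConfigError(f"[trials]: {exc}") from exc

    time = None
    if "time" in data:
        s = data["time"]
        try:
            time = TimeSpec(
                n_timepoints=int(s["n_timepoints"]),
                pattern=s.get("pattern", "constant"),
                correlation=s.get("correlation", "independent"),
                rho=float(s.get("rho", 0.0)),
                random_variance=float(s.get("random_variance", 0.0)),
                labels=tuple(s["labels"]) if "labels" in s else None,
            )
        except (KeyError, ValueError) as exc:
            raise ConfigError(f"[time]: {exc}") from exc

    try:
        return ScenarioConfig(
            family=family, varieties=tuple(varieties), design=design, trials=trials, time=time
        )
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc


# ---------------------------------------------------------------------------
# writing


def _fmt(value) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, str):
        return f'"{value}"'
    if isinstance(value, (tuple, list)):
        return "[" + ", ".join(_fmt(v) for v in value) + "]"
    if isinstance(value, Normal):
        return f"{{mean = {value.mean!r}, variance = {value.variance!r}}}"
    return repr(value)


def _section(name: str, items: dict, array: bool = False) -> list[str]:
    header = f"[[{name}]]" if array else f"[{name}]"
    lines = [header]
    for k, v in items.items():
        if v is not None:
            lines.append(f"{k} = {_fmt(v)}")
    lines.append("")
    return lines


def dump_config(config: ScenarioConfig) -> str:
    """Serialize a scenario back to TOML text (round-trips via parse_config)."""
    lines: list[str] = []
    f = config.family
    lines += _section(
        "distribution",
        {
            "family": f.family,
            "dispersion": f.dispersion,
            "dispersion_scale": f.dispersion_scale if f.family == "poislognorm" else None,
            "n": f.n,
        },
    )
    g = config.design
    lines += _section(
        "design",
        {
            "layout": g.layout,
            "replicates": g.n_replicates,
            "block_variance_count": g.block_variance_count or None,
            "block_variance_zero": g.block_variance_zero or None,
        },
    )
    for v in config.varieties:
        lines += _section(
            "variety",
            {
                "name": v.name,
                "role": v.role,
                "count_effect": v.count_effect,
                "zero_effect": v.zero_effect,
                "n_reference": v.n_reference,
            },
            array=True,
        )
        for attr, sect in (
            ("time_coefficients", "variety.time_coefficients"),
            ("zero_time_coefficients", "variety.zero_time_coefficients"),
        ):
            coeffs = getattr(v, attr)
            if coeffs is not None:
                items = {k: val for k, val in asdict(coeffs).items() if val is not None}
                # asdict turns Normal into a dict; restore for formatting
                items = {
                    k: Normal(**val) if isinstance(val, dict) else val
                    for k, val in items.items()
                }
                lines += _section(sect, items)
    tr = config.trials
    if tr.kind != "single" or tr.gxe_variance is not None:
        lines += _section(
            "trials",
            {
                "kind": tr.kind,
                "n_trials": tr.n_trials if tr.kind == "multiple" else None,
                "n_sites": tr.n_sites,
                "n_years": tr.n_years,
                "trial_variance": tr.trial_variance or None,
                "site_variance": tr.site_variance or None,
                "year_variance": tr.year_variance or None,
                "site_year_variance": tr.site_year_variance or None,
                "gxe_variance": tr.gxe_variance,
                "reference_between_trial_variance": tr.reference_between_trial_variance,
                "reference_within_trial_variance": tr.reference_within_trial_variance,
            },
        )
    if config.time is not None:
        s = config.time
        lines += _section(
            "time",
            {
                "n_timepoints": s.n_timepoints,
                "pattern": s.pattern,
                "correlation": s.correlation,
                "rho": s.rho if s.correlation != "independent" else None,
                "random_variance": s.random_variance or None,
                "labels": s.labels,
            },
        )
    return "\n".join(lines)
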