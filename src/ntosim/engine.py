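"""Dataset simulation: effects -> unit-level (mu, delta) -> responses.

One simulated dataset is a long-format table with one row per
(trial, block/plot, variety, timepoint) combination.  A master seed spawns
named substreams for effect draws and response draws so regression tests stay
stable when unrelated parts of a scenario change, and batches use independent
spawned child streams per dataset.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np
import pandas as pd
from scipy.special import expit

from .distributions import _sample_count_part
from .model import EffectDraw, ScenarioConfig, draw_effects, linear_predictor

__all__ = ["simulate_dataset", "simulate_batch", "aggregate_time", "CSV_COLUMNS"]

CSV_COLUMNS = [
    "trial", "site", "year", "block", "plot", "variety", "role",
    "time", "n", "response", "mu_true", "delta_true",
]


def _seed_sequence(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


def simulate_dataset(
    config: ScenarioConfig,
    seed: "int | np.random.SeedSequence",
    include_truth: bool = True,
) -> pd.DataFrame:
    """Simulate one full trial dataset.

    Returns a long-format DataFrame with columns
    ``trial, site, year, block, plot, variety, role, time, n, response,
    mu_true, delta_true`` (truth columns only when ``include_truth``).
    Bit-reproducible for a given seed.
    """
    ss = _seed_sequence(seed)
    eff_ss, resp_ss = ss.spawn(2)
    draw = draw_effects(config, np.random.default_rng(eff_ss))
    return _sample_responses(config, draw, np.random.default_rng(resp_ss), include_truth)


def _sample_responses(
    config: ScenarioConfig,
    draw: EffectDraw,
    rng: np.random.Generator,
    include_truth: bool,
) -> pd.DataFrame:
    n_trials = config.trials.n_trials
    n_blocks = config.design.n_replicates
    expanded = config.expanded_varieties()
    n_var = len(expanded)
    T = config.time.n_timepoints if config.time is not None else 1

    # full factorial grid in (trial, block, variety, time) order
    trial, block, variety, timepoint = (
        a.ravel() for a in np.meshgrid(
            np.arange(n_trials), np.arange(n_blocks), np.arange(n_var), np.arange(T),
            indexing="ij",
        )
    )
    eta_c, eta_z = linear_predictor(config, draw, trial, block, variety, timepoint)

    fam = config.family
    if fam.is_binary:
        pi = expit(eta_c)
        response = _sample_binary(fam, pi, rng)
        mu_true = fam.n * pi
    else:
        mu_true = np.exp(eta_c)
        response = _sample_count_part(
            fam.family, mu_true, fam.dispersion, fam.dispersion_scale, rng
        )
    if config.has_zero_model:
        delta_true = expit(eta_z)
        response = np.where(rng.random(response.shape) < delta_true, 0, response)
    else:
        delta_true = np.zeros_like(eta_c)

    names = np.array([n for n, _, _ in expanded])
    roles = np.array([r for _, r, _ in expanded])
    site_year = config.trials.trial_index()
    sites = np.array([s if s is not None else -1 for s, _ in site_year])
    years = np.array([y if y is not None else -1 for _, y in site_year])

    is_rcb = config.design.layout == "rcb"
    data = {
        "trial": trial + 1,
        "site": np.where(sites[trial] >= 0, sites[trial] + 1, 0),
        "year": np.where(years[trial] >= 0, years[trial] + 1, 0),
        "block": (block + 1) if is_rcb else np.zeros_like(block),
        "plot": block * n_var + variety + 1,
        "variety": names[variety],
        "role": roles[variety],
        "time": (
            np.asarray(config.time.labels)[timepoint]
            if config.time is not None
            else np.zeros(len(trial))
        ),
        "n": np.full(len(trial), fam.n if fam.is_binary else 1),
        "response": response.astype(np.int64),
    }
    if include_truth:
        data["mu_true"] = mu_true
        data["delta_true"] = delta_true
    return pd.DataFrame(data)


def _sample_binary(fam, pi: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    if fam.family == "binomial" or float(fam.dispersion or 0.0) == 0.0:
        return rng.binomial(fam.n, pi)
    if fam.family == "betabinom":
        phi = float(fam.dispersion)
        a = pi * (1.0 - phi) / phi
        b = (1.0 - pi) * (1.0 - phi) / phi
        return rng.binomial(fam.n, rng.beta(a, b))
    # binlogitnorm: normal random effect on the logit scale
    s2 = float(fam.dispersion)
    from scipy.special import logit as _logit

    p = expit(_logit(pi) + rng.normal(0.0, np.sqrt(s2), pi.shape))
    return rng.binomial(fam.n, p)


def simulate_batch(
    config: ScenarioConfig,
    n_datasets: int,
    master_seed: "int | np.random.SeedSequence",
    include_truth: bool = True,
) -> Iterator[pd.DataFrame]:
    """Yield ``n_datasets`` independent datasets from spawned seed substreams.

    Each dataset redraws every random effect (blocks, reference varieties,
    trial effects, time random vectors); only the fixed effects of the
    scenario stay the same from dataset to dataset.  The k-th dataset is
    reproducible from the master seed alone.
    """
    if n_datasets < 1:
        raise ValueError("n_datasets must be >= 1")
    ss = _seed_sequence(master_seed)
    for child in ss.spawn(n_datasets):
        yield simulate_dataset(config, child, include_truth=include_truth)


def aggregate_time(ds: pd.DataFrame, how: str = "sum") -> pd.DataFrame:
    """Collapse repeated measurements by summing over time per unit.

    Emits one row per experimental unit with ``response`` (and ``mu_true``
    where present) summed over the timepoints; ``time`` is dropped to 0 and
    ``delta_true`` is set to NaN (a summed count has no single structural-zero
    probability).  A dataset with one timepoint is returned unchanged.
    """
    if how != "sum":
        raise ValueError("only how='sum' is supported")
    if ds["time"].nunique() <= 1:
        return ds.copy()
    counts = ds.groupby(["trial", "block", "plot", "variety"])["time"].count()
    if counts.nunique() != 1:
        raise ValueError("missing timepoints: units have unequal numbers of observations")
    keys = ["trial", "site", "year", "block", "plot", "variety", "role", "n"]
    agg = {"response": "sum"}
    if "mu_true" in ds.columns:
        agg["mu_true"] = "sum"
    out = ds.groupby(keys, as_index=False, sort=False).agg(agg)
    out.insert(keys.index("n"), "time", 0.0)
    if "delta_true" in ds.columns:
        out["delta_true"] = np.nan
    return out
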