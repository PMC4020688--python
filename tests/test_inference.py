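"""Difference tests, profile-likelihood ratio CIs and TOST equivalence."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from ntosim import engine, power
from ntosim.inference import (
    IntervalResult,
    fit_count_model,
    loganova_test,
    lrt_difference,
    profile_ci_ratio,
    quasi_poisson_test,
    tost_equivalence,
)


def dataset_from_arrays(gm, comparator, additional=None):
    rows = []
    for name, role, xs in [
        ("gm", "gm", gm),
        ("comparator", "comparator", comparator),
        ("additional1", "additional", additional if additional is not None else []),
    ]:
        for x in xs:
            rows.append({"variety": name, "role": role, "response": int(x), "time": 0.0})
    return pd.DataFrame(rows)


@pytest.fixture
def nb_dataset():
    return engine.simulate_dataset(power.crd_count_config("negbin", 10.0, 2.0, 20, 0.5), 3)


class TestFitCountModel:
    def test_poisson_full_means_are_sample_means(self, nb_dataset):
        fit = fit_count_model(nb_dataset, "poisson", "full")
        observed = nb_dataset.groupby("variety")["response"].mean()
        for name, mu in fit.means.items():
            assert mu == pytest.approx(observed[name])

    def test_null_pools_gm_and_comparator_only(self, nb_dataset):
        fit = fit_count_model(nb_dataset, "negbin", "null")
        sub = nb_dataset[nb_dataset["role"].isin(["gm", "comparator"])]
        assert fit.means["gm"] == fit.means["comparator"]
        assert fit.means["gm"] == pytest.approx(sub["response"].mean())
        assert fit.means["additional1"] == pytest.approx(
            nb_dataset.loc[nb_dataset["role"] == "additional", "response"].mean()
        )

    def test_null_loglik_never_exceeds_full(self):
        for seed in range(8):
            ds = engine.simulate_dataset(
                power.crd_count_config("negbin", 5.0, 1.5, 10, 0.5), seed
            )
            full = fit_count_model(ds, "negbin", "full")
            null = fit_count_model(ds, "negbin", "null")
            assert null.loglik <= full.loglik + 1e-9

    def test_matches_statsmodels_negbin(self, nb_dataset):
        """Independent route: statsmodels NB2 regression with variety dummies
        must find the same maximized log-likelihood and dispersion."""
        sm = pytest.importorskip("statsmodels.api")
        y = nb_dataset["response"].to_numpy()
        X = pd.get_dummies(nb_dataset["variety"], dtype=float).to_numpy()
        res = sm.NegativeBinomial(y, X).fit(disp=0, maxiter=200)
        ours = fit_count_model(nb_dataset, "negbin", "full")
        assert ours.loglik == pytest.approx(res.llf, abs=1e-4)
        assert ours.dispersion == pytest.approx(res.params[-1], rel=1e-3)

    def test_equidispersed_boundary_switches_to_poisson(self):
        ds = dataset_from_arrays([3] * 6, [3] * 6, [3] * 6)
        fit = fit_count_model(ds, "negbin", "full")
        assert fit.dispersion == 0.0

    def test_all_zero_variety_flagged(self):
        ds = dataset_from_arrays([0] * 6, [2, 3, 1, 4, 2, 2], [1] * 6)
        fit = fit_count_model(ds, "negbin", "full")
        assert fit.boundary


class TestDifferenceTests:
    def test_identical_groups_give_zero_statistic(self):
        ds = dataset_from_arrays([1, 5, 2, 4], [1, 5, 2, 4], [3, 3, 3, 3])
        for fn in (lambda d: lrt_difference(d, "negbin"),
                   lambda d: lrt_difference(d, "poisson"),
                   quasi_poisson_test):
            res = fn(ds)
            assert res.statistic == pytest.approx(0.0, abs=1e-6)
            assert res.p_value == pytest.approx(1.0, abs=1e-4)
        assert loganova_test(ds).statistic == pytest.approx(0.0, abs=1e-12)

    def test_quasi_poisson_scaling_rule(self, nb_dataset):
        """The Poisson LRT is divided by the full-model mean deviance exactly
        when that exceeds 1 (recomputed here from first principles)."""
        pois = lrt_difference(nb_dataset, "poisson")
        qp = quasi_poisson_test(nb_dataset)
        means = nb_dataset.groupby("variety")["response"].transform("mean").to_numpy()
        y = nb_dataset["response"].to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            dev = 2 * np.sum(np.where(y > 0, y * np.log(y / means), 0.0) - (y - means))
        mean_dev = dev / (len(y) - 3)
        assert mean_dev > 1  # overdispersed data
        assert qp.statistic == pytest.approx(pois.statistic / mean_dev, rel=1e-9)

    def test_quasi_poisson_no_scaling_when_underdispersed(self):
        ds = dataset_from_arrays([4, 4, 5, 5], [4, 5, 4, 5], [4, 4, 5, 5])
        assert quasi_poisson_test(ds).statistic == pytest.approx(
            lrt_difference(ds, "poisson").statistic, rel=1e-9
        )

    def test_loganova_shift_only_with_zeros(self):
        no_zero = dataset_from_arrays([2, 3, 4, 5], [1, 2, 3, 4], [2, 2, 3, 3])
        with_zero = dataset_from_arrays([0, 3, 4, 5], [1, 2, 3, 4], [2, 2, 3, 3])
        # recompute the contrast by hand for the no-zero case: plain log
        y1 = np.log([2, 3, 4, 5.0])
        y2 = np.log([1, 2, 3, 4.0])
        y3 = np.log([2, 2, 3, 3.0])
        sse = sum(((y - y.mean()) ** 2).sum() for y in (y1, y2, y3))
        s2 = sse / 9
        t = (y1.mean() - y2.mean()) / np.sqrt(s2 * 0.5)
        assert loganova_test(no_zero).statistic == pytest.approx(t, rel=1e-12)
        assert loganova_test(with_zero).statistic != pytest.approx(t, rel=1e-3)

    def test_loganova_type_I_error(self):
        """Size approximately 0.05 on null data whose log is normal-ish."""
        rng = np.random.default_rng(12)
        rejections = 0
        n_sims = 600
        for _ in range(n_sims):
            gm, comp, add = (
                rng.poisson(rng.lognormal(np.log(20), 0.4, 15)) for _ in range(3)
            )
            ds = dataset_from_arrays(gm, comp, add)
            rejections += loganova_test(ds).p_value < 0.05
        rate = rejections / n_sims
        assert rate == pytest.approx(0.05, abs=3 * np.sqrt(0.05 * 0.95 / n_sims))

    def test_nb_power_increases_with_replication(self):
        powers = []
        for n_rep in (6, 40):
            rej = 0
            for seed, ds in enumerate(
                engine.simulate_batch(
                    power.crd_count_config("negbin", 10.0, 2.0, n_rep, 0.5), 120, 5
                )
            ):
                rej += lrt_difference(ds, "negbin").p_value < 0.05
            powers.append(rej / 120)
        assert powers[1] > powers[0] + 0.2


class TestProfileCI:
    def test_theta_hat_inside_interval(self, nb_dataset):
        for family in ("poisson", "negbin"):
            ci = profile_ci_ratio(nb_dataset, family)
            assert 0 < ci.lower <= ci.theta_hat <= ci.upper

    def test_matches_grid_scan_oracle(self):
        """Independent route: scan the Poisson profile log-likelihood on a
        dense theta grid, maximizing the nuisance mean numerically, and read
        off where it crosses the chi-square cutoff."""
        ds = engine.simulate_dataset(power.crd_count_config("poisson", 5.0, 1.5, 10), 17)
        ci = profile_ci_ratio(ds, "poisson")

        by = ds.groupby("role")["response"]
        s1, s2 = by.sum()["gm"], by.sum()["comparator"]
        n1 = n2 = 10

        def prof(theta):
            def nll(mu):
                return -(s1 * np.log(theta * mu) - n1 * theta * mu
                         + s2 * np.log(mu) - n2 * mu)
            res = optimize.minimize_scalar(nll, bounds=(1e-6, 100.0), method="bounded",
                                           options={"xatol": 1e-10})
            return -res.fun

        grid = np.linspace(np.log(ci.lower) - 0.3, np.log(ci.upper) + 0.3, 2001)
        ll = np.array([prof(np.exp(g)) for g in grid])
        inside = 2 * (ll.max() - ll) <= stats.chi2.ppf(0.95, 1)
        assert np.exp(grid[inside][0]) == pytest.approx(ci.lower, abs=2e-3)
        assert np.exp(grid[inside][-1]) == pytest.approx(ci.upper, abs=2e-3)

    def test_narrower_interval_at_lower_level(self, nb_dataset):
        wide = profile_ci_ratio(nb_dataset, "negbin", level=0.95)
        narrow = profile_ci_ratio(nb_dataset, "negbin", level=0.90)
        assert wide.lower < narrow.lower < narrow.upper < wide.upper

    def test_width_shrinks_with_replication(self):
        medians = []
        for n_rep in (4, 10, 40):
            widths = [
                (lambda ci: ci.upper - ci.lower)(profile_ci_ratio(ds, "poisson"))
                for ds in engine.simulate_batch(
                    power.crd_count_config("poisson", 5.0, 1.0, n_rep), 60, 9
                )
            ]
            medians.append(np.median(widths))
        assert medians[0] > medians[1] > medians[2]

    def test_coverage_near_nominal(self):
        """95% profile CI covers the true ratio (theta = 1) about 95% of the
        time for Poisson mu = 5, N = 20."""
        covered = 0
        n_sims = 1000
        for ds in engine.simulate_batch(
            power.crd_count_config("poisson", 5.0, 1.0, 20), n_sims, 123
        ):
            ci = profile_ci_ratio(ds, "poisson")
            covered += ci.lower <= 1.0 <= ci.upper
        rate = covered / n_sims
        assert rate == pytest.approx(0.95, abs=3 * np.sqrt(0.95 * 0.05 / n_sims) + 0.005)


class TestTost:
    def test_inside_limits_is_equivalent(self):
        ci = IntervalResult(1.0, 0.6, 1.8, 0.95)
        assert tost_equivalence(ci, (0.5, 2.0)).equivalent

    def test_crossing_limit_is_not_equivalent(self):
        ci = IntervalResult(0.8, 0.4, 1.2, 0.95)
        assert not tost_equivalence(ci, (0.5, 2.0)).equivalent

    def test_invalid_limits_rejected(self):
        ci = IntervalResult(1.0, 0.8, 1.2, 0.95)
        with pytest.raises(ValueError):
            tost_equivalence(ci, (2.0, 0.5))

    def test_equivalence_probability_matches_exact_enumeration(self):
        """The Poisson sums are sufficient, so P(CI inside limits) can be
        enumerated exactly; the simulated fraction must agree (N = 8, mu = 5,
        theta = 1, limits (1/2, 2); exact value 0.7148 for the 95% CI)."""
        N, mu = 8, 5.0
        lam = N * mu
        ks = np.arange(1, int(lam + 10 * np.sqrt(lam)))
        pk = stats.poisson.pmf(ks, lam)
        exact = 0.0
        for s1, p1 in zip(ks, pk):
            if p1 < 1e-12:
                continue
            for s2, p2 in zip(ks, pk):
                if p2 < 1e-12:
                    continue
                ci = _ci_from_sums(int(s1), int(s2), N, N)
                if 0.5 < ci[0] and ci[1] < 2.0:
                    exact += p1 * p2
        assert exact == pytest.approx(0.7148, abs=2e-3)

        n_sims = 400
        hits = 0
        for ds in engine.simulate_batch(
            power.crd_count_config("poisson", mu, 1.0, N), n_sims, 31
        ):
            ci = profile_ci_ratio(ds, "poisson")
            hits += tost_equivalence(ci, (0.5, 2.0)).equivalent
        assert hits / n_sims == pytest.approx(
            exact, abs=3 * np.sqrt(exact * (1 - exact) / n_sims)
        )


def _ci_from_sums(s1, s2, n1, n2, level=0.95):
    """Poisson ratio CI straight from the sufficient statistics (independent
    of the package's implementation)."""
    crit = stats.chi2.ppf(level, 1)

    def prof(lt):
        th = np.exp(lt)
        mu = (s1 + s2) / (n1 * th + n2)
        return s1 * (lt + np.log(mu)) - n1 * th * mu + s2 * np.log(mu) - n2 * mu

    lt_hat = np.log((s1 / n1) / (s2 / n2))
    ll_hat = prof(lt_hat)

    def g(lt):
        return 2 * (ll_hat - prof(lt)) - crit

    lo = optimize.brentq(g, lt_hat - 8, lt_hat, xtol=1e-9)
    hi = optimize.brentq(g, lt_hat, lt_hat + 8, xtol=1e-9)
    return np.exp(lo), np.exp(hi)
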