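"""Scenario assembly: time polynomials, correlation structures, effect draws."""

import numpy as np
import pytest
from scipy.special import expit

from ntosim.model import (
    DesignSpec,
    FamilySpec,
    Normal,
    ScenarioConfig,
    TimeCoefficients,
    TimeSpec,
    TrialStructure,
    VarietySpec,
    correlation_matrix,
    draw_effects,
    linear_predictor,
    quad_coefficients,
)


class TestQuadCoefficients:
    def test_forms_agree_on_a_grid(self):
        b0, b1, b2 = quad_coefficients(1.5, 3.0, -8.0)
        t = np.linspace(-20, 20, 41)
        peak = 1.5 - (t - 3.0) ** 2 / (2 * -8.0)
        poly = b0 + b1 * t + b2 * t**2
        assert np.max(np.abs(peak - poly)) < 1e-12

    def test_tolerance_from_relative_abundance_constraint(self):
        # a peak at t=0 falling to 0.6*mu at t = +/-7 days pins down the
        # tolerance: -(7^2)/(2*beta_tol) = log(0.6)  =>  beta_tol = 47.96
        beta_tol = -(7.0**2) / (2.0 * np.log(0.6))
        assert round(beta_tol, 2) == 47.96
        # and implies a relative mean of 0.13 at t = +/-14 days
        b0, b1, b2 = quad_coefficients(0.0, 0.0, beta_tol)
        assert round(float(np.exp(b0 + b1 * 14 + b2 * 14**2)), 2) == 0.13

    def test_infinite_tolerance_limit_is_constant(self):
        b0, b1, b2 = quad_coefficients(2.0, 5.0, 1e12)
        assert b1 == pytest.approx(0.0, abs=1e-10)
        assert b2 == pytest.approx(0.0, abs=1e-10)
        assert b0 == pytest.approx(2.0, abs=1e-10)

    def test_zero_tolerance_rejected(self):
        with pytest.raises(ValueError):
            quad_coefficients(1.0, 0.0, 0.0)


class TestCorrelationMatrix:
    def test_ar1_powers(self):
        V = correlation_matrix(TimeSpec(3, correlation="ar1", rho=0.8))
        expected = [[1, 0.8, 0.64], [0.8, 1, 0.8], [0.64, 0.8, 1]]
        assert np.allclose(V, expected)

    @pytest.mark.parametrize("corr", ["ar1", "equal"])
    def test_zero_rho_is_identity(self, corr):
        V = correlation_matrix(TimeSpec(4, correlation=corr, rho=0.0))
        assert np.array_equal(V, np.eye(4))

    def test_equal_rho_one_is_shared_effect(self):
        V = correlation_matrix(TimeSpec(3, correlation="equal", rho=1.0))
        assert np.array_equal(V, np.ones((3, 3)))

    def test_non_psd_equal_correlation_rejected(self):
        with pytest.raises(ValueError):
            correlation_matrix(TimeSpec(3, correlation="equal", rho=-0.9))

    def test_ar1_rho_out_of_range(self):
        with pytest.raises(ValueError):
            correlation_matrix(TimeSpec(3, correlation="ar1", rho=1.5))


class TestScenarioValidation:
    def test_requires_gm_and_comparator(self):
        with pytest.raises(ValueError, match="gm and one comparator"):
            ScenarioConfig(
                family=FamilySpec("poisson"),
                varieties=(VarietySpec("a", "gm", 0.1),),
                design=DesignSpec("crd", 4),
            )

    def test_crd_cannot_carry_block_variance(self):
        with pytest.raises(ValueError, match="crd"):
            DesignSpec("crd", 4, block_variance_count=0.5)

    def test_reference_population_needs_size(self):
        with pytest.raises(ValueError, match="n_reference"):
            VarietySpec("ref", "reference_population", Normal(1, 1))


class TestDrawEffects:
    def test_zero_variances_give_zero_effects(self, simple_crd, rng):
        draw = draw_effects(simple_crd, rng)
        assert np.all(draw.block_count == 0)
        assert np.all(draw.env_count == 0)
        # fixed effects survive as the realized variety effects
        assert draw.variety_count[0].tolist() == pytest.approx(
            [np.log(8.0), np.log(4.0), np.log(4.0)]
        )

    def test_same_seed_same_draw(self, worked_example_config):
        d1 = draw_effects(worked_example_config, np.random.default_rng(5))
        d2 = draw_effects(worked_example_config, np.random.default_rng(5))
        assert np.array_equal(d1.variety_count, d2.variety_count)
        assert np.array_equal(d1.block_zero, d2.block_zero)

    def test_two_stage_reference_variance_adds(self):
        """Law of total variance: marginal reference-effect variance across
        trials is s1^2 + s2^2."""
        config = ScenarioConfig(
            family=FamilySpec("poisson"),
            varieties=(
                VarietySpec("gm", "gm", 0.0),
                VarietySpec("comparator", "comparator", 0.0),
                VarietySpec("ref", "reference_population", Normal(1.0, 1.0), n_reference=2),
            ),
            design=DesignSpec("crd", 2),
            trials=TrialStructure(
                "multiple", n_trials=2,
                reference_between_trial_variance=0.5,
                reference_within_trial_variance=0.2,
            ),
        )
        rng = np.random.default_rng(0)
        draws = np.array(
            [draw_effects(config, rng).variety_count[:, 2:] for _ in range(4000)]
        )
        assert draws.mean() == pytest.approx(1.0, abs=0.05)
        assert draws.var() == pytest.approx(0.7, abs=0.06)
        # within one trial the two references share the trial mean M
        within = draws[:, 0, 0] - draws[:, 0, 1]
        assert within.var() == pytest.approx(2 * 0.2, abs=0.05)

    def test_variety_order_permutation_invariance(self, rng):
        """Random draws are keyed by variety identity (sorted-name order), so
        permuting the config list leaves each variety's realized effect law
        unchanged draw-for-draw."""
        def make(order):
            vs = {
                "gm": VarietySpec("gm", "gm", 0.4),
                "comparator": VarietySpec("comparator", "comparator", 0.5),
                "ref": VarietySpec(
                    "ref", "reference_population", Normal(1.0, 1.0), n_reference=3
                ),
            }
            return ScenarioConfig(
                family=FamilySpec("poisson"),
                varieties=tuple(vs[k] for k in order),
                design=DesignSpec("rcb", 2, 0.1),
            )

        a = draw_effects(make(["gm", "comparator", "ref"]), np.random.default_rng(9))
        b = draw_effects(make(["ref", "comparator", "gm"]), np.random.default_rng(9))
        fa = dict(zip(a.varieties, a.variety_count[0]))
        fb = dict(zip(b.varieties, b.variety_count[0]))
        assert fa == fb

    def test_gxe_draws_vary_across_trials(self):
        config = ScenarioConfig(
            family=FamilySpec("poisson"),
            varieties=(
                VarietySpec("gm", "gm", 1.0),
                VarietySpec("comparator", "comparator", 1.0),
            ),
            design=DesignSpec("crd", 2),
            trials=TrialStructure("multiple", n_trials=50, gxe_variance=0.25),
        )
        draw = draw_effects(config, np.random.default_rng(3))
        gm = draw.variety_count[:, draw.varieties.index("gm")]
        assert gm.std() == pytest.approx(0.5, rel=0.4)
        assert gm.mean() == pytest.approx(1.0, abs=0.25)


class TestLinearPredictor:
    def test_worked_example_grid(self, worked_example_config):
        """Fixed effects plus the quoted random draws reproduce the published
        5-variety x 2-block grid of exp()/expit() expressions exactly."""
        config = worked_example_config
        draw = draw_effects(config, np.random.default_rng(0))
        draw.variety_count[0] = [0.4, 0.5, 0.8, 0.9, 1.2]
        draw.variety_zero[0] = [-0.3, -0.2, -1.2, -0.9, -0.6]
        draw.block_count[0] = [-0.4, 0.1]
        draw.block_zero[0] = [-0.1, 0.2]

        variety_effects = [0.4, 0.5, 0.8, 0.9, 1.2]
        zero_effects = [-0.3, -0.2, -1.2, -0.9, -0.6]
        for j in range(5):
            eta_c, eta_z = linear_predictor(config, draw, 0, [0, 1], j)
            mu = np.exp(eta_c)
            delta = expit(eta_z)
            assert mu[0] == pytest.approx(np.exp(variety_effects[j] - 0.4), rel=1e-12)
            assert mu[1] == pytest.approx(np.exp(variety_effects[j] + 0.1), rel=1e-12)
            assert delta[0] == pytest.approx(expit(zero_effects[j] - 0.1), rel=1e-12)
            assert delta[1] == pytest.approx(expit(zero_effects[j] + 0.2), rel=1e-12)
        # spot values printed in the example: GM block 1 and reference 3 block 2
        eta_c, eta_z = linear_predictor(config, draw, 0, 0, 0)
        assert np.exp(eta_c) == pytest.approx(1.0)
        assert expit(eta_z) == pytest.approx(0.4013, abs=5e-5)
        eta_c, _ = linear_predictor(config, draw, 0, 1, 4)
        assert np.exp(eta_c) == pytest.approx(3.6693, abs=5e-5)

    def test_time_polynomial_enters_predictor(self):
        tc = TimeCoefficients(beta_max=np.log(10.0), beta_opt=0.0, beta_tol=47.96)
        config = ScenarioConfig(
            family=FamilySpec("poisson"),
            varieties=(
                VarietySpec("gm", "gm", time_coefficients=tc),
                VarietySpec("comparator", "comparator", time_coefficients=tc),
            ),
            design=DesignSpec("crd", 2),
            time=TimeSpec(5, "quadratic", labels=(-14, -7, 0, 7, 14)),
        )
        draw = draw_effects(config, np.random.default_rng(1))
        eta, _ = linear_predictor(config, draw, 0, 0, 0, [0, 1, 2, 3, 4])
        mu = np.exp(eta)
        assert mu[2] == pytest.approx(10.0, rel=1e-9)  # peak at t = 0
        assert mu[1] / 10.0 == pytest.approx(0.6, abs=1e-3)  # 0.6*mu at +/-7
        assert mu[0] / 10.0 == pytest.approx(0.13, abs=5e-3)  # 0.13*mu at +/-14
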