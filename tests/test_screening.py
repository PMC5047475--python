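"""Trendline fitting, correlation significance and the screening gate."""

import numpy as np
import pytest

from cystindex import (
    GateConfig,
    correlation_p_value,
    fit_family,
    fit_linear,
    paired_series,
    screen_all,
    screen_variable,
)
from cystindex.errors import (
    ConfigError,
    DegeneratePredictorError,
    FamilyInapplicableError,
    InsufficientDataError,
)
from cystindex.screening import passing_names
from cystindex.study import PairedSeries


def series(x, y, name="v"):
    return PairedSeries(name, np.asarray(x, float), np.asarray(y, float))


class TestFitLinear:
    def test_perfect_line(self):
        fit = fit_linear(series([1, 2, 3, 4], [1, 2, 3, 4]))
        assert fit.slope == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)
        assert fit.r == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.p_value == 0.0

    def test_hand_computed_normal_equations(self):
        # x=[1,2,3], y=[2,4,7]: slope = 5/2, intercept = 13/3 - 5 = -2/3
        fit = fit_linear(series([1, 2, 3], [2, 4, 7]))
        assert fit.slope == pytest.approx(2.5)
        assert fit.intercept == pytest.approx(-2.0 / 3.0)

    def test_negative_slope_gives_negative_r(self):
        fit = fit_linear(series([1, 2, 3, 4], [8, 6.5, 4, 2]))
        assert fit.slope < 0
        assert fit.r < 0
        assert abs(fit.r) == pytest.approx(np.sqrt(fit.r_squared))

    def test_bun_equation_from_study(self, fixture_table):
        fit = fit_linear(paired_series(fixture_table, "bun"))
        assert fit.n == 27
        assert round(fit.slope, 2) == 0.95
        assert round(fit.intercept, 2) == -8.15

    def test_constant_predictor_rejected(self):
        with pytest.raises(DegeneratePredictorError):
            fit_linear(series([2, 2, 2], [1, 2, 3]))

    def test_too_few_points(self):
        with pytest.raises(InsufficientDataError):
            fit_linear(series([1, 2], [1, 2]))


class TestFitFamily:
    def test_exponential_exact(self):
        x = np.arange(1.0, 6.0)
        fit = fit_family(series(x, np.exp(x)), "exponential")
        assert fit.r_squared == pytest.approx(1.0)
        amplitude, rate = fit.coefficients
        assert amplitude == pytest.approx(1.0)
        assert rate == pytest.approx(1.0)

    def test_exponential_inapplicable_at_zero_response(self):
        with pytest.raises(FamilyInapplicableError):
            fit_family(series([1, 2, 3], [0, 1, 2]), "exponential")

    def test_logarithmic_exact(self):
        x = np.array([1.0, 2.0, 4.0, 8.0])
        fit = fit_family(series(x, 3.0 * np.log(x) + 1.0), "logarithmic")
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.coefficients[0] == pytest.approx(3.0)
        assert fit.coefficients[1] == pytest.approx(1.0)

    def test_logarithmic_inapplicable_at_nonpositive_x(self):
        with pytest.raises(FamilyInapplicableError):
            fit_family(series([0, 1, 2], [1, 2, 3]), "logarithmic")

    def test_polynomial2_exact_interpolation(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        fit = fit_family(series(x, x**2), "polynomial2")
        assert fit.coefficients[0] == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_polynomial2_needs_four_points(self):
        with pytest.raises(FamilyInapplicableError):
            fit_family(series([1, 2, 3], [1, 4, 9]), "polynomial2")

    def test_nonlinear_r_is_sqrt_r_squared(self, fixture_table):
        s = paired_series(fixture_table, "bun")
        for family in ("exponential", "logarithmic", "polynomial2"):
            fit = fit_family(s, family)
            assert fit.r >= 0
            assert fit.r == pytest.approx(np.sqrt(fit.r_squared))


class TestCorrelationPValue:
    def test_study_kidney_mass_significance(self):
        # r = 0.73 at n = 27 is significant well below the 1% level
        assert correlation_p_value(0.73, 27) < 0.01

    def test_zero_correlation(self):
        assert correlation_p_value(0.0, 10) == pytest.approx(1.0)

    def test_tabulated_t_distribution_value(self):
        # t = 0.5*sqrt(8)/sqrt(0.75) = 1.633 on 8 df -> two-tailed p ~ 0.141
        assert correlation_p_value(0.5, 10) == pytest.approx(0.141, abs=1e-3)

    def test_perfect_correlation(self):
        assert correlation_p_value(1.0, 5) == 0.0
        assert correlation_p_value(-1.0, 5) == 0.0

    def test_monotone_in_r_and_n(self):
        rs = np.linspace(0.05, 0.95, 10)
        ps = [correlation_p_value(r, 20) for r in rs]
        assert all(a > b for a, b in zip(ps, ps[1:]))
        ns = [5, 10, 20, 40, 80]
        ps = [correlation_p_value(0.4, n) for n in ns]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_invalid_inputs(self):
        with pytest.raises(InsufficientDataError):
            correlation_p_value(0.5, 2)
        with pytest.raises(ConfigError):
            correlation_p_value(1.5, 10)


class TestScreening:
    def test_serum_cystatin_c_rejected(self, fixture_decisions):
        """The study's null example: no correlation between CI and serum
        Cystatin C."""
        decision = next(
            d for d in fixture_decisions if d.variable_name == "cystatin_c_serum"
        )
        assert not decision.passed
        assert abs(decision.best_fit.r) < 0.5  # nowhere near the 0.7 gate

    def test_bun_passes_with_linear_choice(self, fixture_decisions):
        decision = next(d for d in fixture_decisions if d.variable_name == "bun")
        assert decision.passed
        assert decision.chosen.family == "linear"
        # the best family is curved, but the linear fit is within the margin
        assert decision.linear_preference_applied
        assert abs(decision.best_fit.r) - abs(decision.linear_fit.r) <= 0.10

    def test_fluid_biomarker_selection_matches_study(self, fixture_decisions):
        """Exactly BUN, SCr and 24-h urine IL-18 survive among serum/urine
        biomarkers."""
        assert set(passing_names(fixture_decisions, ("serum", "urine"))) == {
            "bun",
            "scr",
            "il18_urine",
        }

    def test_mass_variables_also_pass(self, fixture_decisions):
        passed = set(passing_names(fixture_decisions))
        assert {"kidney_mass", "kidney_body_mass_ratio"} <= passed

    def test_kidney_mass_linear_r(self, fixture_decisions):
        decision = next(
            d for d in fixture_decisions if d.variable_name == "kidney_mass"
        )
        fit = decision.linear_fit
        assert round(fit.r, 2) == 0.73
        assert fit.n == 27
        assert fit.p_value < 0.01

    def test_pure_noise_rejected(self):
        from cystindex.study import AnimalRecord, BiomarkerSpec, StudyTable

        rng = np.random.default_rng(7)
        ci = rng.uniform(0.4, 35, 27)
        noise = rng.lognormal(0, 1, 27)
        table = StudyTable(
            tuple(
                AnimalRecord(str(i), float(ci[i]), {"noise": float(noise[i])})
                for i in range(27)
            ),
            (BiomarkerSpec("noise", "urine", "a.u."),),
        )
        decision = screen_variable(table, "noise")
        assert not decision.passed

    def test_overstrict_gate_rejects_everything(self, fixture_table):
        decisions = screen_all(fixture_table, GateConfig(r_min=0.99))
        assert passing_names(decisions) == []

    def test_decisions_in_panel_order(self, fixture_table, fixture_decisions):
        assert [d.variable_name for d in fixture_decisions] == list(
            fixture_table.panel_names
        )

    def test_gate_config_validation(self):
        with pytest.raises(ConfigError):
            GateConfig(r_min=1.5)
        with pytest.raises(ConfigError):
            GateConfig(families=("logarithmic",))
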