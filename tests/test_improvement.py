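import numpy as np
import pytest
from scipy.stats import norm

from triarm import (
    ModelParams,
    conditional_mu_draws,
    odds_of_improvement,
    prob_improvement,
    slope_exceedance,
)
from triarm.improvement import build_report, display_odds


class TestProbImprovement:
    def test_symmetric_draws_give_half(self):
        rng = np.random.default_rng(0)
        draws = 5.0 + rng.standard_normal(200_000)
        assert prob_improvement(draws, 5.0, "increase") == pytest.approx(0.5, abs=0.01)

    def test_all_draws_beyond_anchor(self):
        assert prob_improvement(np.array([2.0, 3.0]), 1.0, "increase") == 1.0
        assert prob_improvement(np.array([2.0, 3.0]), 1.0, "decrease") == 0.0

    def test_gaussian_tail_matches_closed_form(self):
        rng = np.random.default_rng(1)
        x = 10.0
        draws = (x + 1.0) + rng.standard_normal(400_000)  # mean one SD above anchor
        assert prob_improvement(draws, x, "increase") == pytest.approx(
            norm.cdf(1.0), abs=0.005
        )

    def test_shift_monotonicity(self):
        rng = np.random.default_rng(2)
        draws = rng.standard_normal(5000)
        p0 = prob_improvement(draws, 0.0, "increase")
        p1 = prob_improvement(draws + 0.3, 0.0, "increase")
        assert p1 >= p0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            prob_improvement(np.array([]), 0.0, "increase")


class TestOdds:
    @pytest.mark.parametrize(
        "p_a,p_b,expected",
        [(0.257, 0.001, 257.0), (0.978, 0.002, 489.0), (0.5, 0.5, 1.0)],
    )
    def test_ratio_arithmetic(self, p_a, p_b, expected):
        assert odds_of_improvement(p_a, p_b) == pytest.approx(expected)

    def test_zero_denominator_is_infinite_not_crash(self):
        assert odds_of_improvement(0.3, 0.0) == float("inf")
        assert display_odds(float("inf")) == "inf"

    def test_chain_rule_to_machine_precision(self):
        a, b, c = 0.8, 0.25, 0.05
        assert odds_of_improvement(a, b) * odds_of_improvement(b, c) == pytest.approx(
            odds_of_improvement(a, c), rel=1e-14
        )

    def test_display_rounding(self):
        assert display_odds(27.48) == "27"
        assert display_odds(2.46) == "2.5"
        assert display_odds(4.24) == "4.2"
        assert display_odds(489.0) == "489"


class TestConditionalMuDraws:
    def test_degenerate_draws_are_a_point_mass(self, make_degenerate_results):
        res = make_degenerate_results(
            "postSPIC",
            ModelParams(mu=5.0, alpha_single=2.0, beta=1.0, gamma_single=0.1,
                        beta_fam=0.5, sigma=3.0, nu=10.0),
        )
        mu = conditional_mu_draws(res, "single", pre_value=50.0, familiarity=3.0)
        expected = 5.0 + 2.0 + 1.1 * 50.0 + 0.5 * 3.0
        assert np.all(mu == pytest.approx(expected))

    def test_control_depends_only_on_mu_beta_fam(self, make_degenerate_results):
        base = dict(beta=1.0, beta_fam=0.5, sigma=3.0, nu=10.0)
        res_a = make_degenerate_results("postSPIC", ModelParams(mu=5.0, **base))
        res_b = make_degenerate_results(
            "postSPIC",
            ModelParams(mu=5.0, alpha_single=100.0, gamma_multiple=-2.0, **base),
        )
        mu_a = conditional_mu_draws(res_a, "control", pre_value=40.0)
        mu_b = conditional_mu_draws(res_b, "control", pre_value=40.0)
        np.testing.assert_array_equal(mu_a, mu_b)

    def test_interaction_shifts_single_arm_by_gamma_times_x(self, make_degenerate_results):
        res = make_degenerate_results(
            "postPRCA24",
            ModelParams(mu=0.0, beta=1.0, gamma_single=0.2, sigma=3.0, nu=10.0),
        )
        x = 100.0
        mu_s = conditional_mu_draws(res, "single", pre_value=x)
        mu_c = conditional_mu_draws(res, "control", pre_value=x)
        assert mu_s[0] - mu_c[0] == pytest.approx(0.2 * x)

    def test_control_probability_depends_on_shifted_predictor_sign(
        self, make_degenerate_results
    ):
        """For fixed parameters the control-arm improvement at anchor x is
        decided by the sign of mu + (beta - 1) x + beta_fam * f."""
        params = ModelParams(mu=4.0, beta=0.9, beta_fam=0.5, sigma=3.0, nu=10.0)
        res = make_degenerate_results("postSPIC", params)
        for x in (20.0, 60.0, 96.0):
            shifted = params.mu + (params.beta - 1.0) * x + params.beta_fam * 3.0
            mu = conditional_mu_draws(res, "control", pre_value=x, familiarity=3.0)
            p = prob_improvement(mu, x, "increase")
            assert p == (1.0 if shifted > 0 else 0.0)

    def test_stai_rejects_conditioning_value(self, make_degenerate_results):
        res = make_degenerate_results(
            "postSTAI", ModelParams(mu=20.0, beta_fam=0.0, sigma=3.0, nu=10.0)
        )
        with pytest.raises(ValueError, match="no pre covariate"):
            conditional_mu_draws(res, "control", pre_value=20.0)

    def test_out_of_scale_anchor_rejected(self, make_degenerate_results):
        res = make_degenerate_results(
            "postPRCA24", ModelParams(mu=0.0, beta=1.0, sigma=3.0, nu=10.0)
        )
        with pytest.raises(ValueError, match="outside scale"):
            conditional_mu_draws(res, "control", pre_value=200.0)

    def test_beta_outcome_maps_back_to_original_scale(self, make_degenerate_results):
        res = make_degenerate_results(
            "postIAT", ModelParams(mu=0.0, beta=0.0, phi=10.0)
        )
        mu = conditional_mu_draws(res, "control", pre_value=0.0)
        # eta = 0 -> normalized mean 0.5 -> raw IAT scale midpoint 0
        assert mu[0] == pytest.approx(0.0, abs=1e-12)
        assert -2 <= mu[0] <= 2


class TestSlopeExceedance:
    def test_point_mass_slope(self, make_degenerate_results):
        res = make_degenerate_results(
            "postPRCA24", ModelParams(mu=0.0, beta=2.0, sigma=3.0, nu=10.0)
        )
        assert slope_exceedance(res, "single", 1.0) == 1.0
        assert slope_exceedance(res, "single", 2.5) == 0.0

    def test_gaussian_slope_tail(self, ref_dataset):
        """With Gaussian slope draws and the threshold one SD below their
        mean, the exceedance probability approaches the normal tail."""
        from triarm import BayesianOutcomeModel, PosteriorDraws
        from triarm.results import OutcomeResults

        model = BayesianOutcomeModel.from_dataset("postPRCA24", ref_dataset)
        rng = np.random.default_rng(4)
        n = 100_000
        draws = np.zeros((2, n // 2, len(model.param_names)))
        j_beta = model.param_names.index("beta")
        draws[:, :, j_beta] = rng.standard_normal((2, n // 2)) + 2.0
        draws[:, :, model.param_names.index("sigma")] = 1.0
        draws[:, :, model.param_names.index("nu")] = 10.0
        res = OutcomeResults(model, PosteriorDraws(model.param_names, draws))
        assert slope_exceedance(res, "control", 1.0) == pytest.approx(
            norm.cdf(1.0), abs=0.01
        )

    def test_no_covariate_rejected(self, make_degenerate_results):
        res = make_degenerate_results(
            "postSTAI", ModelParams(mu=20.0, beta_fam=0.0, sigma=3.0, nu=10.0)
        )
        with pytest.raises(ValueError, match="no pre covariate"):
            slope_exceedance(res, "single", 1.0)


class TestBuildReport:
    def test_report_grid_structure(self, make_degenerate_results):
        fits = _point_mass_fits(make_degenerate_results)
        rep = build_report(fits)
        probs = rep.probabilities
        assert set(probs.outcome) == set(fits)
        # PRCA24 reported at middle/highest with "<"; others at lowest/middle
        prca = probs[probs.outcome == "postPRCA24"]
        assert set(prca.anchor) == {"middle", "highest"}
        assert (prca.direction == "decrease").all()
        iat = probs[probs.outcome == "postIAT"]
        assert set(iat.anchor) == {"lowest", "middle"}
        assert (iat.direction == "increase").all()
        assert len(probs) == 5 * 2 * 3
        assert len(rep.odds) == 5 * 2 * 3
        assert ((rep.probabilities.probability >= 0) & (rep.probabilities.probability <= 1)).all()
        assert (rep.odds.odds >= 0).all()
        # STAI has no covariate hence no slope rows
        assert "postSTAI" not in set(rep.slopes.outcome)

    def test_missing_outcome_listed_by_name(self, make_degenerate_results):
        fits = _point_mass_fits(make_degenerate_results)
        del fits["afterSPIC"]
        with pytest.raises(KeyError, match="afterSPIC"):
            build_report(fits)

    def test_strong_single_arm_effect_raises_single_probability(
        self, make_degenerate_results
    ):
        fits = _point_mass_fits(make_degenerate_results)
        # strong positive single-arm main effect on postSPIC
        fits["postSPIC"] = make_degenerate_results(
            "postSPIC",
            ModelParams(mu=0.0, alpha_single=40.0, beta=1.0, beta_fam=0.0,
                        sigma=5.0, nu=10.0),
        )
        rep = build_report(fits)
        p_single = rep.probability("postSPIC", "single", "middle")
        p_control = rep.probability("postSPIC", "control", "middle")
        assert p_single > p_control


def _point_mass_fits(make_degenerate_results):
    return {
        "postIAT": make_degenerate_results(
            "postIAT", ModelParams(mu=0.1, beta=0.5, phi=10.0)
        ),
        "postPRCA24": make_degenerate_results(
            "postPRCA24", ModelParams(mu=1.0, beta=0.95, sigma=8.0, nu=20.0)
        ),
        "postSPIC": make_degenerate_results(
            "postSPIC", ModelParams(mu=2.0, beta=1.0, beta_fam=0.2, sigma=9.0, nu=20.0)
        ),
        "afterSPIC": make_degenerate_results(
            "afterSPIC", ModelParams(mu=-1.0, beta=1.0, beta_fam=0.2, sigma=9.0, nu=20.0)
        ),
        "postSTAI": make_degenerate_results(
            "postSTAI", ModelParams(mu=20.0, beta_fam=0.1, sigma=4.0, nu=20.0)
        ),
    }
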