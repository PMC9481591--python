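"""Design assembly, the mixed-effects fit and its oracles, prediction, CV."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from deplife import (SplineSpec, build_design, default_hazard,
                     fit_poisson_mixed, generate_tracts, goodness_of_fit,
                     model_from_json, model_to_json, predict_rates,
                     select_knots, simulate_counts)
from deplife.model import prediction_rows
from tests.conftest import ORACLE_KNOTS

# Independent Laplace fit of the oracle dataset's male design (150 areas,
# mean population 5,000, 2011-2013, generator seeds 11/12, knots
# (2,22,42,67,82)) obtained with R glmmTMB 1.1.9; small discrepancies are
# expected because that implementation also profiles the Laplace determinant
# term when updating the fixed effects.
GLMMTMB_SIGMA = 0.07302179
GLMMTMB_LOGLIK = -8865.492
GLMMTMB_BETA = np.array([
    -6.95154199, 0.03424964, 0.14907603, -0.28356920, 0.12174872,
    -0.58335685, -0.97431206, 2.31366853, 0.23005451, -0.02313240,
    0.05561446, -0.14446861, 0.15540953, -0.04144048, 0.09155619,
    -0.22528260, 0.22423951, 0.03196314, -0.19414132, 0.48638652,
    -0.38994403, -0.02120113, -0.01874130, 0.09117126, -0.12491972,
])


class TestBuildDesign:
    def test_column_count_for_eight_knots(self, oracle_male):
        d = build_design(oracle_male, SplineSpec())
        assert d.X.shape[1] == 1 + 7 + 4 + 28
        assert d.column_names[0] == "intercept"
        assert d.column_names[-1] == "Q5:rcs7"

    def test_reference_quintile_rows_have_zero_dummy_columns(self, oracle_male):
        d = build_design(oracle_male, SplineSpec())
        q1 = d.meta["quintile"].to_numpy() == "Q1"
        assert np.all(d.X[q1][:, 8:] == 0.0)

    def test_offset_is_log_person_years(self, oracle_male):
        d = build_design(oracle_male, SplineSpec())
        assert np.allclose(d.offset, np.log(oracle_male["population"]))

    def test_open_band_uses_configured_representative_age(self, oracle_male):
        d = build_design(oracle_male, SplineSpec(), open_band_age=92.0)
        open_rows = oracle_male["age_upper"].isna().to_numpy()
        assert np.all(d.meta.loc[open_rows, "age"] == 92.0)

    def test_pooled_sexes_and_unknown_quintiles_rejected(self, oracle_counts):
        with pytest.raises(ValueError, match="per sex"):
            build_design(oracle_counts, SplineSpec())
        bad = oracle_counts[oracle_counts["sex"] == "male"].copy()
        bad.loc[bad.index[0], "quintile"] = "Q9"
        with pytest.raises(ValueError, match="Q9"):
            build_design(bad, SplineSpec())


class TestFit:
    def test_sigma_zero_reduces_to_plain_glm(self, oracle_male):
        d = build_design(oracle_male, SplineSpec(ORACLE_KNOTS))
        mine = fit_poisson_mixed(d, sigma_u=0.0)
        glm = sm.GLM(d.y, d.X, family=sm.families.Poisson(),
                     offset=d.offset).fit()
        assert np.max(np.abs(mine.beta - glm.params)) < 1e-6

    def test_matches_independent_laplace_implementation(self, oracle_male_model):
        m = oracle_male_model
        assert m.sigma_u == pytest.approx(GLMMTMB_SIGMA, abs=5e-4)
        assert np.max(np.abs(m.beta - GLMMTMB_BETA)) < 5e-3
        assert m.loglik == pytest.approx(GLMMTMB_LOGLIK, abs=0.1)

    def test_outer_objective_is_nondecreasing(self, oracle_male_model):
        hist = oracle_male_model.objective_history
        assert len(hist) > 1
        assert np.all(np.diff(hist) >= 0)

    def test_row_splitting_leaves_estimates_unchanged(self, oracle_male):
        spec = SplineSpec(ORACLE_KNOTS)
        whole = fit_poisson_mixed(build_design(oracle_male, spec))
        half = oracle_male.copy()
        half["population"] /= 2
        half["deaths"] = 0
        split = pd.concat([oracle_male.assign(population=half["population"]),
                           half], ignore_index=True)
        refit = fit_poisson_mixed(build_design(split, spec))
        assert np.max(np.abs(refit.beta - whole.beta)) < 1e-4
        assert refit.sigma_u == pytest.approx(whole.sigma_u, abs=1e-4)

    def test_total_fitted_deaths_match_observed(self, oracle_male_model,
                                                oracle_male):
        d = build_design(oracle_male, SplineSpec(ORACLE_KNOTS))
        u = oracle_male_model.area_intercepts.loc[
            d.meta["area_id"]].to_numpy()
        fitted = np.exp(d.X @ oracle_male_model.beta + u + d.offset)
        assert fitted.sum() == pytest.approx(d.y.sum(), rel=1e-6)

    def test_area_intercepts_center_near_zero(self, oracle_male_model):
        u = oracle_male_model.area_intercepts
        assert abs(u.mean()) < 0.02
        assert oracle_male_model.sigma_u > 0

    def test_rank_deficiency_raises_with_column_names(self, oracle_male):
        single_band = oracle_male[oracle_male["age_lower"] == 60]
        with pytest.raises(ValueError, match="rcs"):
            build_design_and_fit = fit_poisson_mixed(
                build_design(single_band, SplineSpec(ORACLE_KNOTS)))

    def test_too_few_areas_raise(self, oracle_male):
        one_area = oracle_male[oracle_male["area_id"] == "A001"]
        with pytest.raises(ValueError, match="areas"):
            fit_poisson_mixed(build_design(one_area, SplineSpec(ORACLE_KNOTS)))


class TestPredict:
    def test_zero_covariance_collapses_the_interval(self, oracle_male_model):
        import dataclasses
        degenerate = dataclasses.replace(
            oracle_male_model,
            vcov_beta=np.zeros_like(oracle_male_model.vcov_beta))
        out = predict_rates(degenerate, [50.0], "Q2")
        assert out.loc[0, "ci_low"] == out.loc[0, "rate"] == out.loc[0, "ci_high"]

    def test_interval_brackets_rate_on_the_rate_scale(self, oracle_male_model):
        out = predict_rates(oracle_male_model, np.arange(0, 101, 10.0), "Q4")
        assert (out["ci_low"] < out["rate"]).all()
        assert (out["rate"] < out["ci_high"]).all()
        assert (out["ci_low"] > 0).all()

    def test_area_prediction_scales_by_its_intercept(self, oracle_male_model):
        area = oracle_male_model.area_intercepts.index[3]
        u = float(oracle_male_model.area_intercepts.loc[area])
        base = predict_rates(oracle_male_model, [70.0], "Q1")
        tract = predict_rates(oracle_male_model, [70.0], "Q1", area_id=area)
        assert tract.loc[0, "rate"] == pytest.approx(
            base.loc[0, "rate"] * np.exp(u))

    def test_mean_mode_applies_lognormal_correction(self, oracle_male_model):
        med = predict_rates(oracle_male_model, [70.0], "Q1", mode="median")
        mean = predict_rates(oracle_male_model, [70.0], "Q1", mode="mean")
        factor = np.exp(oracle_male_model.sigma_u ** 2 / 2)
        assert mean.loc[0, "rate"] == pytest.approx(
            med.loc[0, "rate"] * factor)

    def test_out_of_range_age_and_unknown_area_raise(self, oracle_male_model):
        with pytest.raises(ValueError):
            predict_rates(oracle_male_model, [111.0], "Q1")
        with pytest.raises(KeyError):
            predict_rates(oracle_male_model, [50.0], "Q1", area_id="nope")

    def test_predicted_log_rate_linear_beyond_boundary_knots(self,
                                                             oracle_male_model):
        ages = np.arange(83.0, 109.0)
        out = predict_rates(oracle_male_model, ages, "Q3")
        second = np.diff(np.log(out["rate"].to_numpy()), 2)
        assert np.max(np.abs(second)) < 1e-10


class TestSelectKnots:
    def test_single_candidate_is_returned_unchanged(self, oracle_male):
        res = select_knots(oracle_male, [ORACLE_KNOTS], seed=1)
        assert res.chosen.knots == ORACLE_KNOTS
        assert len(res.cv_table) == 1

    def test_duplicate_candidates_score_identically(self, oracle_male):
        res = select_knots(oracle_male, [ORACLE_KNOTS, ORACLE_KNOTS], seed=1)
        assert res.cv_table["cv_mae"].nunique() == 1

    def test_deterministic_given_seed(self, oracle_male):
        a = select_knots(oracle_male, [ORACLE_KNOTS, (2.0, 42.0, 82.0)], seed=7)
        b = select_knots(oracle_male, [ORACLE_KNOTS, (2.0, 42.0, 82.0)], seed=7)
        pd.testing.assert_frame_equal(a.cv_table, b.cv_table)


class TestGoodnessOfFit:
    def test_refit_on_own_fitted_counts_has_tiny_mae(self, oracle_male,
                                                     oracle_male_model):
        d = build_design(oracle_male, SplineSpec(ORACLE_KNOTS))
        u = oracle_male_model.area_intercepts.loc[d.meta["area_id"]].to_numpy()
        fitted = np.exp(d.X @ oracle_male_model.beta + u + d.offset)
        synth = oracle_male.copy()
        synth["deaths"] = fitted
        refit = fit_poisson_mixed(build_design(synth, SplineSpec(ORACLE_KNOTS)),
                                  sigma_u=oracle_male_model.sigma_u)
        table, mae = goodness_of_fit(refit, synth)
        assert mae < 1e-4

    def test_output_covers_all_bands_and_quintiles(self, oracle_male,
                                                   oracle_male_model):
        table, _ = goodness_of_fit(oracle_male_model, oracle_male)
        assert len(table) == 18 * 5


class TestModelComparison:
    def test_interaction_model_fits_adult_gradient_better(self, default_counts):
        """With an age-varying deprivation effect in the truth, the full
        interaction model beats the proportional (no-interaction) variant on
        observed-vs-fitted MAE at adult ages."""
        male = default_counts[default_counts["sex"] == "male"]
        full = fit_poisson_mixed(build_design(male, SplineSpec()))
        reduced = fit_poisson_mixed(
            build_design(male, SplineSpec(), interactions=False))
        tab_full, _ = goodness_of_fit(full, male)
        tab_red, _ = goodness_of_fit(reduced, male)
        adult_f = tab_full[tab_full["age"] > 20]
        adult_r = tab_red[tab_red["age"] > 20]
        mae_f = np.abs(adult_f["observed_rate"] - adult_f["fitted_rate"]).mean()
        mae_r = np.abs(adult_r["observed_rate"] - adult_r["fitted_rate"]).mean()
        assert mae_f < mae_r

    def test_quintile_log_effects_recovered_within_three_ses(self):
        """With age-constant quintile effects the dummy coefficients recover
        the true log rate ratios within 3 standard errors."""
        from deplife.hazards import HazardSpec
        effects = (0.0, 0.1, 0.2, 0.3, 0.4)
        h = HazardSpec(2e-4, 2.35e-5, 0.0975, quintile_log_effects=effects,
                       frailty_sd=0.1)
        tracts = generate_tracts(500, seed=77)
        counts = simulate_counts(tracts, {"male": h, "female": h}, seed=78)
        model = fit_poisson_mixed(
            build_design(counts[counts["sex"] == "male"], SplineSpec()))
        se = np.sqrt(np.diag(model.vcov_beta))
        for qi, q in enumerate(("Q2", "Q3", "Q4", "Q5"), start=1):
            j = model.column_names.index(q)
            assert abs(model.beta[j] - effects[qi]) < 3 * se[j], q


class TestSerialization:
    def test_round_trip_preserves_predictions(self, oracle_male_model, tmp_path):
        path = tmp_path / "model.json"
        model_to_json(oracle_male_model, path)
        back = model_from_json(path)
        ages = np.arange(0, 101, 5.0)
        a = predict_rates(oracle_male_model, ages, "Q5")
        b = predict_rates(back, ages, "Q5")
        pd.testing.assert_frame_equal(a, b)
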