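"""Weighted logistic propensity fitting, stepwise selection, and scoring."""

import numpy as np
import pandas as pd
import pytest

from webpsa.propensity import (
    StageSpec,
    backward_stepwise,
    build_design,
    fit_weighted_logistic,
    run_stages,
    score_participants,
)


def two_by_two(web_exposed=30, web_unexposed=70, ref_exposed=10, ref_unexposed=90):
    rows = (
        [{"source": "web", "x": "yes"}] * web_exposed
        + [{"source": "web", "x": "no"}] * web_unexposed
        + [{"source": "reference", "x": "yes"}] * ref_exposed
        + [{"source": "reference", "x": "no"}] * ref_unexposed
    )
    return pd.DataFrame(rows)


class TestWeightedLogistic:
    def test_saturated_binary_model_matches_closed_form_log_odds_ratio(self):
        data = two_by_two()
        X, by_var, mask = build_design(data, ["x"])
        fit = fit_weighted_logistic(
            X, (data["source"] == "web").astype(int), np.ones(len(data)), by_var
        )
        expected = np.log((30 * 90) / (70 * 10))
        assert fit.params["x[yes]"] == pytest.approx(expected, abs=1e-8)

    def test_independent_covariate_has_null_coefficient(self):
        data = two_by_two(50, 50, 50, 50)
        X, by_var, _ = build_design(data, ["x"])
        fit = fit_weighted_logistic(
            X, (data["source"] == "web").astype(int), np.ones(len(data)), by_var
        )
        assert fit.params["x[yes]"] == pytest.approx(0.0, abs=1e-8)
        assert fit.variable_pvalue("x") > 0.9

    def test_weight_scale_invariance(self):
        data = two_by_two()
        X, by_var, _ = build_design(data, ["x"])
        y = (data["source"] == "web").astype(int)
        a = fit_weighted_logistic(X, y, np.ones(len(data)), by_var).params
        b = fit_weighted_logistic(X, y, 2.0 * np.ones(len(data)), by_var).params
        assert np.allclose(a, b, atol=1e-8)


class TestBackwardStepwise:
    def test_strong_candidate_retained_noise_candidate_removed(self):
        rng = np.random.default_rng(0)
        n = 4_000
        signal = np.where(rng.random(n) < 0.5, "a", "b")
        member = rng.random(n) < np.where(signal == "a", 0.6, 0.4)
        data = pd.DataFrame(
            {
                "source": np.where(member, "web", "reference"),
                "signal": signal,
                "noise": np.where(rng.random(n) < 0.5, "u", "v"),
            }
        )
        fit = backward_stepwise(data, np.ones(n), forced=[], candidates=["signal", "noise"])
        assert "signal" in fit.selected
        assert "noise" not in fit.selected
        assert all(fit.pvalues[v] < 0.05 for v in fit.selected)

    def test_matches_independent_stepwise_oracle_on_three_candidates(self):
        """Replay the removal sequence with statsmodels directly and check the
        same final model emerges, and that every removal was the current
        maximum p-value >= alpha."""
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        n = 2_000
        data = pd.DataFrame(
            {
                "c1": np.where(rng.random(n) < 0.5, "a", "b"),
                "c2": np.where(rng.random(n) < 0.4, "a", "b"),
                "c3": np.where(rng.random(n) < 0.6, "a", "b"),
            }
        )
        eta = -0.1 + 0.4 * (data["c1"] == "a")
        data["source"] = np.where(
            rng.random(n) < 1 / (1 + np.exp(-eta)), "web", "reference"
        )
        y = (data["source"] == "web").astype(float)

        def oracle_pvalues(candidates):
            X = pd.DataFrame({"const": np.ones(n)})
            for c in candidates:
                X[c] = (data[c] == "b").astype(float)
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit(cov_type="HC0")
            return {c: float(res.pvalues[c]) for c in candidates}

        remaining = ["c1", "c2", "c3"]
        while remaining:
            pv = oracle_pvalues(remaining)
            worst = max(remaining, key=lambda c: (pv[c], remaining.index(c)))
            if pv[worst] < 0.05:
                break
            remaining.remove(worst)

        fit = backward_stepwise(
            data, np.ones(n), forced=[], candidates=["c1", "c2", "c3"]
        )
        assert sorted(fit.selected) == sorted(remaining)

    def test_forced_variables_never_removed(self):
        rng = np.random.default_rng(1)
        n = 500
        data = pd.DataFrame(
            {
                "source": np.where(rng.random(n) < 0.5, "web", "reference"),
                "noise": np.where(rng.random(n) < 0.5, "u", "v"),
            }
        )
        fit = backward_stepwise(data, np.ones(n), forced=["noise"], candidates=[])
        assert fit.selected == ("noise",)

    def test_candidate_order_invariance_without_ties(self, small_scenario):
        sc = small_scenario
        ref = sc["reference"][sc["reference"]["gender"] == "male"]
        web = sc["web"][sc["web"]["gender"] == "male"].copy()
        web["base_weight"] = 1.0
        data = pd.concat([ref, web], ignore_index=True)
        w = data["base_weight"].to_numpy()
        cands = ["age_group", "region", "education", "partnership"]
        a = backward_stepwise(data, w, [], cands)
        b = backward_stepwise(data, w, [], cands[::-1])
        assert sorted(a.selected) == sorted(b.selected)


class TestRunStages:
    def test_stage_nesting_and_identity_selection(self, male_run):
        fits = male_run["fits"]
        assert [f.stage for f in fits] == [1, 2, 3, 4, 5]
        for prev, cur in zip(fits, fits[1:]):
            assert set(prev.selected) <= set(cur.selected)
        # identity drives selection in the scenario, so stage 2 must pick it up
        assert "sexual_identity" in fits[1].selected

    def test_gender_separation(self, small_scenario):
        sc = small_scenario
        ref, web = sc["reference"], sc["web"].copy()
        web["base_weight"] = 1.0
        spec = StageSpec({1: ("age_group",), 2: ("sexual_identity",), 3: (), 4: (), 5: ()})
        base = run_stages(ref, web, spec, "male")
        females = web[web["gender"] == "female"].sample(frac=1, random_state=1)
        web_shuffled = pd.concat([web[web["gender"] == "male"], females], ignore_index=True)
        perm = run_stages(ref, web_shuffled, spec, "male")
        for a, b in zip(base, perm):
            assert a.selected == b.selected
            assert np.allclose(a.params, b.params)

    def test_empty_stratum_errors(self, small_scenario):
        sc = small_scenario
        web = sc["web"].copy()
        web["base_weight"] = 1.0
        ref_males_only = sc["reference"][sc["reference"]["gender"] == "male"]
        with pytest.raises(ValueError, match="empty gender stratum"):
            run_stages(ref_males_only, web, StageSpec({1: (), 2: (), 3: (), 4: (), 5: ()}), "female")


class TestScoring:
    def test_intercept_only_scores_equal_weighted_web_fraction(self):
        data = two_by_two()
        fit = backward_stepwise(data, np.ones(len(data)), forced=[], candidates=[])
        scores = score_participants(fit, data)
        assert np.allclose(scores, 0.5)  # 100 web of 200

    def test_mean_score_equals_weighted_web_fraction(self, male_run):
        """Score-equation identity of weighted logistic regression."""
        ref, web = male_run["reference"], male_run["web"]
        fit = male_run["fits"][4]
        combined = pd.concat([ref, web], ignore_index=True)
        scores = score_participants(fit, combined)
        w = combined["base_weight"].to_numpy()
        web_frac = w[combined["source"] == "web"].sum() / w.sum()
        assert np.average(scores, weights=w) == pytest.approx(web_frac, abs=1e-6)

    def test_missing_covariate_gives_missing_score(self):
        data = two_by_two()
        fit = backward_stepwise(data, np.ones(len(data)), forced=["x"], candidates=[])
        data2 = data.copy()
        data2.loc[0, "x"] = np.nan
        scores = score_participants(fit, data2)
        assert np.isnan(scores.iloc[0])
        assert scores.iloc[1:].notna().all()


class TestStageSpec:
    def test_exactly_five_stages_required(self):
        with pytest.raises(ValueError, match="1..5"):
            StageSpec({1: ("a",), 2: ("b",)})

    def test_overlapping_pools_rejected(self):
        with pytest.raises(ValueError, match="repeats"):
            StageSpec({1: ("a",), 2: ("a",), 3: (), 4: (), 5: ()})
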