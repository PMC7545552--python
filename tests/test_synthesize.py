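"""Generator checks against the exact cell-enumeration oracle."""

import numpy as np
import pandas as pd
import pytest

from webpsa.synthesize import (
    CategoricalModel,
    ConfigurationError,
    LogitModel,
    PopulationSpec,
    cell_bernoulli_probability,
    data_dictionary,
    draw_reference_sample,
    draw_web_panel,
    enumerate_cells,
    generate_population,
    inject_missing,
)


def tiny_spec(n=50_000, seed=0, outcome=None, selection=None):
    return PopulationSpec(
        n_population=n,
        demographics={
            "gender": CategoricalModel(("male", "female"), {"male": 0.5, "female": 0.5}),
            "age_group": CategoricalModel(("young", "old"), {"young": 0.4, "old": 0.6}),
        },
        identity={
            "sexual_identity": CategoricalModel(
                ("heterosexual", "gay_or_bisexual"),
                {"heterosexual": 0.95, "gay_or_bisexual": 0.05},
            )
        },
        lifestyle={},
        attitudes={},
        behaviours={},
        outcomes={"y": outcome or LogitModel(np.log(0.3 / 0.7))},
        selection_model=selection or LogitModel(-2.0),
        seed=seed,
    )


class TestGeneratePopulation:
    def test_marginal_prevalences_match_spec(self):
        pop = generate_population(tiny_spec())
        n = len(pop)
        # binomial 3-SE bounds around the specified cell probabilities
        assert abs((pop["y"].mean()) - 0.3) < 3 * np.sqrt(0.3 * 0.7 / n)
        p_id = (pop["sexual_identity"] == "gay_or_bisexual").mean()
        assert abs(p_id - 0.05) < 3 * np.sqrt(0.05 * 0.95 / n)

    def test_outcome_prevalence_matches_enumeration_oracle(self):
        outcome = LogitModel(-1.0, {("sexual_identity", "gay_or_bisexual"): 1.2})
        spec = tiny_spec(outcome=outcome)
        cells = enumerate_cells(spec)
        expected = float(
            (cells["probability"] * cell_bernoulli_probability(cells, outcome)).sum()
        )
        pop = generate_population(spec)
        se = np.sqrt(expected * (1 - expected) / len(pop))
        assert abs(pop["y"].mean() - expected) < 4 * se

    def test_identical_seeds_identical_tables(self):
        a = generate_population(tiny_spec(n=2_000, seed=7))
        b = generate_population(tiny_spec(n=2_000, seed=7))
        assert a.to_csv(index=False) == b.to_csv(index=False)

    @pytest.mark.parametrize(
        "bad_probs", [{"male": 0.6, "female": 0.5}, {"male": -0.1, "female": 1.1}]
    )
    def test_invalid_distribution_names_field(self, bad_probs):
        spec = tiny_spec()
        spec.demographics["gender"] = CategoricalModel(("male", "female"), bad_probs)
        with pytest.raises(ConfigurationError, match="gender"):
            spec.validate()


class TestReferenceSample:
    def test_equal_probability_weights_are_one(self):
        pop = generate_population(tiny_spec(n=5_000))
        ref = draw_reference_sample(pop, 500, seed=1)
        assert np.allclose(ref["base_weight"], 1.0)
        assert (ref["source"] == "reference").all()
        assert ref["participant_id"].is_unique

    def test_unequal_inclusion_halves_the_oversampled_cells_weight(self):
        pop = generate_population(tiny_spec(n=20_000))
        ref = draw_reference_sample(
            pop, 2_000, seed=2, inclusion={("age_group", "young"): 2.0}
        )
        w_young = ref.loc[ref["age_group"] == "young", "base_weight"].iloc[0]
        w_old = ref.loc[ref["age_group"] == "old", "base_weight"].iloc[0]
        assert w_young == pytest.approx(w_old / 2)
        assert ref["base_weight"].mean() == pytest.approx(1.0)

    def test_weighted_prevalence_recovers_population(self):
        spec = tiny_spec(n=50_000)
        pop = generate_population(spec)
        ref = draw_reference_sample(
            pop, 5_000, seed=3, inclusion={("age_group", "young"): 2.0}
        )
        w = ref["base_weight"].to_numpy()
        target = pop["y"].mean()
        est = np.sum(w * ref["y"].to_numpy()) / w.sum()
        assert abs(est - target) < 4 * np.sqrt(target * (1 - target) / len(ref))

    def test_oversized_request_errors(self):
        pop = generate_population(tiny_spec(n=100))
        with pytest.raises(ValueError, match="exceeds population"):
            draw_reference_sample(pop, 101, seed=0)


class TestWebPanel:
    def test_intercept_only_selection_is_simple_random_sampling(self):
        spec = tiny_spec(n=50_000)
        pop = generate_population(spec)
        web = draw_web_panel(pop, 2_000, LogitModel(-3.0), seed=4)
        for var, level in [("gender", "male"), ("age_group", "young"), ("y", 1)]:
            p_pop = (pop[var] == level).mean()
            p_web = (web[var] == level).mean()
            assert abs(p_web - p_pop) < 4 * np.sqrt(p_pop * (1 - p_pop) / len(web))

    def test_selected_prevalence_matches_bayes_enumeration(self):
        sel = LogitModel(-4.0, {("sexual_identity", "gay_or_bisexual"): 1.5})
        spec = tiny_spec(n=50_000, selection=sel)
        pop = generate_population(spec)
        cells = enumerate_cells(spec)
        s = cell_bernoulli_probability(cells, sel)
        post = cells["probability"] * s
        post = post / post.sum()  # P(cell | selected) by Bayes over discrete cells
        expected = float(
            post[cells["sexual_identity"] == "gay_or_bisexual"].sum()
        )
        web = draw_web_panel(pop, 2_000, sel, seed=5)
        observed = (web["sexual_identity"] == "gay_or_bisexual").mean()
        assert observed > (pop["sexual_identity"] == "gay_or_bisexual").mean()
        assert abs(observed - expected) < 4 * np.sqrt(expected * (1 - expected) / len(web))

    def test_outcomes_downstream_of_identity_are_biased_before_adjustment(self):
        outcome = LogitModel(-1.0, {("sexual_identity", "gay_or_bisexual"): 1.5})
        sel = LogitModel(-4.0, {("sexual_identity", "gay_or_bisexual"): 2.0})
        spec = tiny_spec(n=50_000, outcome=outcome, selection=sel)
        pop = generate_population(spec)
        web = draw_web_panel(pop, 2_000, sel, seed=6)
        assert web["y"].mean() > pop["y"].mean() + 2 * np.sqrt(0.25 / len(web))

    def test_all_zero_propensities_error(self):
        pop = generate_population(tiny_spec(n=100))
        with pytest.raises(ValueError, match="propensities"):
            draw_web_panel(pop, 10, LogitModel(-np.inf), seed=0)


class TestMissingnessAndDictionary:
    def test_mcar_injection_rate(self):
        pop = generate_population(tiny_spec(n=20_000))
        out = inject_missing(pop, {"age_group": 0.1}, seed=9)
        rate = out["age_group"].isna().mean()
        assert abs(rate - 0.1) < 4 * np.sqrt(0.1 * 0.9 / len(out))
        assert out["gender"].notna().all()

    def test_population_spec_yaml_round_trip(self, tmp_path):
        import yaml

        from webpsa.scenarios import default_population_spec
        from webpsa.synthesize import spec_from_dict, spec_to_dict

        spec = default_population_spec(seed=3, n_population=500)
        path = tmp_path / "population.yaml"
        path.write_text(yaml.safe_dump(spec_to_dict(spec)))
        loaded = spec_from_dict(yaml.safe_load(path.read_text()))
        a = generate_population(spec)
        b = generate_population(loaded)
        assert a.to_csv(index=False) == b.to_csv(index=False)

    def test_data_dictionary_roles(self):
        dd = data_dictionary(tiny_spec())
        assert dd["gender"]["role"] == "demographic"
        assert dd["sexual_identity"]["role"] == "identity"
        assert dd["y"] == {"role": "outcome", "levels": [0, 1]}
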