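"""Quintile subclassification, PSA ratios, and the matching invariant."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from webpsa.psa import (
    SubclassingError,
    apply_psa_weights,
    compute_psa_ratios,
    make_subclasses,
)


class TestMakeSubclasses:
    def test_hundred_distinct_scores_give_five_groups_of_twenty(self):
        scores = pd.Series(np.arange(1, 101) / 101.0)
        sub = make_subclasses(scores)
        sizes = sub.assignment.value_counts()
        assert sorted(sizes) == [20] * 5

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(0.01, 0.99), min_size=5, max_size=200, unique=True))
    def test_distinct_score_subclass_sizes_differ_by_at_most_one(self, values):
        sub = make_subclasses(pd.Series(values))
        sizes = sub.assignment.value_counts()
        assert len(sizes) == 5
        assert sizes.max() - sizes.min() <= 1

    def test_tie_at_boundary_goes_to_lower_subclass(self):
        # 20th percentile of 1..10 scaled is the 2nd value; a repeat of that
        # value must land in subclass 1, not 2
        scores = pd.Series([0.1, 0.2, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9])
        sub = make_subclasses(scores)
        assert (sub.assignment.iloc[[1, 2]] == 1.0).all()

    def test_all_equal_scores_collapse_to_single_passthrough_subclass(self):
        sub = make_subclasses(pd.Series([0.4] * 50))
        assert sub.degenerate
        assert (sub.assignment == 1.0).all()

    def test_binary_scores_form_two_tie_groups(self):
        scores = pd.Series([0.2] * 60 + [0.7] * 40)
        sub = make_subclasses(scores)
        assert sub.n_subclasses == 2
        assert (sub.assignment[:60] == 1.0).all()
        assert (sub.assignment[60:] == 2.0).all()

    def test_missing_scores_left_unassigned(self):
        scores = pd.Series(np.linspace(0.1, 0.9, 30))
        scores.iloc[3] = np.nan
        sub = make_subclasses(scores)
        assert np.isnan(sub.assignment.iloc[3])
        assert sub.assignment.drop(index=3).notna().all()

    def test_weighted_quintiles_shift_boundaries(self):
        scores = pd.Series(np.linspace(0.01, 0.99, 100))
        weights = pd.Series(np.r_[np.full(50, 10.0), np.full(50, 1.0)])
        unweighted = make_subclasses(scores)
        weighted = make_subclasses(scores, weights=weights)
        assert (weighted.boundaries < unweighted.boundaries).all()


class TestPsaRatios:
    def make(self, ref_sub, web_sub, ref_w=None, web_w=None):
        assignment = pd.Series(
            np.concatenate([ref_sub, web_sub]).astype(float))
        source = pd.Series(["reference"] * len(ref_sub) + ["web"] * len(web_sub))
        weights = pd.Series(
            np.concatenate(
                [
                    ref_w if ref_w is not None else np.ones(len(ref_sub)),
                    web_w if web_w is not None else np.ones(len(web_sub)),
                ]
            )
        )
        boundaries = np.arange(1, int(assignment.max())) + 0.5

        class FakeSub:
            pass

        sub = FakeSub()
        sub.assignment = assignment
        sub.boundaries = boundaries
        sub.ids = lambda: np.arange(1, int(assignment.max()) + 1, dtype=float)
        return sub, source, weights

    def test_worked_proportions_example(self):
        # reference (0.3,0.2,0.2,0.2,0.1) vs web (0.1,0.2,0.2,0.2,0.3)
        ref = np.repeat([1, 2, 3, 4, 5], [30, 20, 20, 20, 10])
        web = np.repeat([1, 2, 3, 4, 5], [10, 20, 20, 20, 30])
        sub, source, weights = self.make(ref, web)
        ratios = compute_psa_ratios(sub, source, weights)
        assert np.allclose(ratios, [3.0, 1.0, 1.0, 1.0, 1 / 3])

    def test_identical_distributions_give_unit_ratios(self):
        ref = np.repeat([1, 2, 3, 4, 5], 20)
        sub, source, weights = self.make(ref, ref)
        assert np.allclose(compute_psa_ratios(sub, source, weights), 1.0)

    def test_web_weight_scale_invariance(self):
        rng = np.random.default_rng(0)
        ref = rng.integers(1, 6, 200)
        web = rng.integers(1, 6, 150)
        web_w = rng.uniform(0.5, 2.0, 150)
        sub, source, weights = self.make(ref, web, web_w=web_w)
        r1 = compute_psa_ratios(sub, source, weights)
        sub2, source2, weights2 = self.make(ref, web, web_w=7.3 * web_w)
        r2 = compute_psa_ratios(sub2, source2, weights2)
        assert np.allclose(r1, r2)

    def test_empty_subclass_for_one_source_errors(self):
        ref = np.repeat([1, 2, 3, 4, 5], 20)
        web = np.repeat([1, 2, 3, 4], 20)  # no web in subclass 5
        sub, source, weights = self.make(ref, web)
        with pytest.raises(SubclassingError, match="no web"):
            compute_psa_ratios(sub, source, weights)

    def test_non_overlapping_scores_error(self):
        # all web scores above all reference scores -> bottom subclass pure reference
        scores = pd.Series(np.r_[np.linspace(0.1, 0.4, 80), np.linspace(0.6, 0.9, 20)])
        sub = make_subclasses(scores)
        source = pd.Series(["reference"] * 80 + ["web"] * 20)
        with pytest.raises(SubclassingError, match="no web"):
            compute_psa_ratios(sub, source, pd.Series(np.ones(100)))


class TestApplyWeights:
    def test_unit_ratios_preserve_initial_weights(self):
        web = pd.DataFrame({"base_weight": [1.0, 2.0, 0.5]})
        assignment = pd.Series([1.0, 2.0, 1.0])
        ratios = pd.Series([1.0, 1.0], index=[1.0, 2.0])
        out = apply_psa_weights(web, assignment, ratios, pd.Series(np.nan, index=web.index))
        assert np.allclose(out, web["base_weight"])

    def test_product_rule(self):
        web = pd.DataFrame({"base_weight": [1.2]})
        out = apply_psa_weights(
            web,
            pd.Series([3.0]),
            pd.Series([2.0, 1.0, 3.0], index=[1.0, 2.0, 3.0]),
            pd.Series(np.nan, index=web.index),
        )
        assert out.iloc[0] == pytest.approx(3.6)

    def test_missing_score_uses_fallback(self):
        web = pd.DataFrame({"base_weight": [1.0, 1.0]})
        assignment = pd.Series([1.0, np.nan])
        ratios = pd.Series([2.0], index=[1.0])
        fallback = pd.Series([np.nan, 1.4])
        out = apply_psa_weights(web, assignment, ratios, fallback)
        assert out.iloc[1] == pytest.approx(1.4)


class TestMatchingInvariant:
    def test_psa_weighted_web_subclass_distribution_matches_reference(self, male_run):
        """The construction guarantees exact matching of the weighted subclass
        distributions at every stage."""
        from webpsa.validation import _subclass_distributions

        for stage, ref_dist, web_dist in _subclass_distributions(male_run):
            assert float((ref_dist - web_dist).abs().max()) < 1e-12

    def test_base_weight_scale_invariance_of_final_relative_weights(self, male_run, small_scenario):
        from webpsa.psa import psa_weights_for_stage

        ref = male_run["reference"]
        web = male_run["web"]
        fit = male_run["fits"][1]
        ps = male_run["post_stratification"]
        base = psa_weights_for_stage(fit, ref, web, ps.weights)
        ref_scaled = ref.copy()
        ref_scaled["base_weight"] *= 5.0
        scaled = psa_weights_for_stage(fit, ref_scaled, web, ps.weights)
        assert np.allclose(base.final_weights, scaled.final_weights)
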