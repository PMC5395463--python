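"""Model-set analysis: enumeration against a brute-force oracle, Akaike
weights, adjusted importance, and the variable-reduction screen."""

from itertools import combinations
from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from jointabund import assembly, synth
from jointabund.mixedmodel import ModelSpec
from jointabund.modelset import (
    ModelSetSummary,
    adjusted_importance,
    akaike_weights,
    enumerate_models,
    evidence_ratio,
    fit_model_set,
    format_er,
    variable_reduction,
)
from jointabund.terms import all_components, expand_terms


def brute_force_term_sets(candidates, max_effects, forbidden=frozenset()):
    """Independent subset generator: frozensets of hierarchy-complete terms."""
    out = set()
    for k in range(max_effects + 1):
        for sub in combinations(candidates, k):
            terms = expand_terms(sub)
            comps = all_components(terms)
            if any(set(p) <= comps for p in forbidden):
                continue
            out.add(frozenset(terms))
    return out


class TestEnumeration:
    def test_three_candidates_max_two_gives_seven_specs(self):
        specs = enumerate_models(["A", "B", "C"], max_effects=2)
        assert len(specs) == 7
        assert {frozenset(s.effect_terms) for s in specs} == brute_force_term_sets(
            ["A", "B", "C"], 2
        )
        assert all(s.include_survey for s in specs)

    def test_forbidden_pair_removes_exactly_its_models(self):
        specs = enumerate_models(
            ["A", "B", "C"], max_effects=2, forbidden_pairs={("A", "B")}
        )
        assert len(specs) == 6
        assert {frozenset(s.effect_terms) for s in specs} == brute_force_term_sets(
            ["A", "B", "C"], 2, forbidden={("A", "B")}
        )

    def test_interaction_candidate_expands_hierarchy(self):
        specs = enumerate_models(["A:year"], max_effects=1)
        full = [s for s in specs if s.effect_terms]
        assert len(full) == 1
        assert full[0].effect_terms == ("A", "year", "A:year")

    def test_forbidden_pair_inherited_by_interactions(self):
        specs = enumerate_models(
            ["A:year", "B"], max_effects=2, forbidden_pairs={("A", "B")}
        )
        joint = [
            s
            for s in specs
            if {"A", "B"} <= all_components(s.effect_terms)
        ]
        assert joint == []

    def test_matches_oracle_up_to_six_candidates(self):
        cands = ["A", "B", "C:year", "D", "E", "F:year"]
        forb = {("A", "D"), ("C", "F")}
        specs = enumerate_models(
            cands, max_effects=4, forbidden_pairs=forb, max_fixed_params=None
        )
        got = {frozenset(s.effect_terms) for s in specs}
        want = brute_force_term_sets(cands, 4, forbidden=forb)
        assert got == want

    def test_fixed_parameter_cap_enforced(self):
        # two cropland-by-year interactions share "year": exactly 8 fixed
        # parameters (1 + 2 survey contrasts + 5 slopes) -> allowed; adding
        # any further effect exceeds the cap
        specs = enumerate_models(
            ["A:year", "B:year", "C"], max_effects=3, max_fixed_params=8
        )
        sets = {frozenset(s.effect_terms) for s in specs}
        both = frozenset({"A", "B", "year", "A:year", "B:year"})
        assert both in sets
        assert not any(s >= both | {"C"} for s in sets)

    def test_deduplicates_equivalent_candidates(self):
        specs = enumerate_models(["A:B", "B:A"], max_effects=2)
        assert len(specs) == 2  # empty + one interaction spec

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            enumerate_models([])


def _stub_summary(weights, term_sets):
    fits = [
        SimpleNamespace(spec=ModelSpec.from_candidates(list(ts))) for ts in term_sets
    ]
    models = pd.DataFrame({"weight": np.asarray(weights, float)})
    return ModelSetSummary(models=models, fits=fits)


class TestWeightsAndImportance:
    def test_equal_aicc_equal_weights(self):
        assert np.allclose(akaike_weights([100.0, 100.0]), [0.5, 0.5])

    def test_two_unit_gap_closed_form(self):
        w = akaike_weights([100.0, 102.0])
        expect = np.array([1.0, np.exp(-1.0)])
        assert np.allclose(w, expect / expect.sum(), atol=1e-4)
        assert w[0] == pytest.approx(0.7311, abs=1e-4)

    def test_weights_match_direct_formula(self):
        rng = np.random.default_rng(2)
        a = rng.uniform(100, 130, 5)
        w = akaike_weights(a)
        direct = np.exp(-(a - a.min()) / 2)
        direct /= direct.sum()
        assert np.allclose(w, direct, atol=1e-12)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        shift=st.floats(min_value=-1e3, max_value=1e3),
        n=st.integers(min_value=2, max_value=8),
    )
    def test_weights_shift_invariant(self, shift, n):
        rng = np.random.default_rng(n)
        a = rng.uniform(0, 30, n)
        assert np.allclose(
            akaike_weights(a), akaike_weights(a + shift), atol=1e-12
        )

    def test_evidence_ratio_basics(self):
        assert evidence_ratio(0.5, 0.5) == 1.0
        assert evidence_ratio(0.5, 0.0) == np.inf
        # two models 2 AICc apart have weight ratio e^1
        w = akaike_weights([100.0, 102.0])
        assert evidence_ratio(w[0], w[1]) == pytest.approx(np.e, rel=1e-12)

    def test_large_gap_renders_above_100(self):
        # 174.2-unit gap: evidence ratio astronomically beyond the cap
        w = akaike_weights([0.0, 174.2])
        assert format_er(evidence_ratio(w[0], w[1])) == ">100"
        assert format_er(2.0) == "2.00"
        assert format_er(1.0) == "1.00"

    def test_adjusted_importance_hand_enumeration(self):
        # 3 models, weights (.5, .3, .2), A only in model 1:
        # A = .5/1, B = (.3+.2)/2 = .25, p = .5/.75 = 2/3, er = 2
        summary = _stub_summary([0.5, 0.3, 0.2], [("A",), ("B",), ("C",)])
        imp = adjusted_importance(summary, ["A"]).set_index("covariate")
        assert imp.loc["A", "adj_probability"] == pytest.approx(2 / 3)
        assert imp.loc["A", "adj_er"] == pytest.approx(2.0)

    def test_saturated_covariate(self):
        summary = _stub_summary([0.6, 0.4], [("A",), ("A", "B")])
        imp = adjusted_importance(summary, ["A", "B"]).set_index("covariate")
        assert imp.loc["A", "adj_probability"] == 1.0
        assert format_er(imp.loc["A", "adj_er"]) == ">100"

    def test_unrepresented_covariate_not_scored(self):
        summary = _stub_summary([1.0], [("A",)])
        imp = adjusted_importance(summary, ["A", "Z"])
        assert list(imp["covariate"]) == ["A"]

    def test_half_representation_equals_raw_weight_sum(self):
        # every covariate in exactly half the models: p_j == raw weight sum
        term_sets = [("A",), ("A", "B"), ("B",), ()]
        weights = [0.4, 0.3, 0.2, 0.1]
        imp = adjusted_importance(
            _stub_summary(weights, term_sets), ["A", "B"]
        ).set_index("covariate")
        assert imp.loc["A", "adj_probability"] == pytest.approx(0.7, abs=1e-12)
        assert imp.loc["B", "adj_probability"] == pytest.approx(0.5, abs=1e-12)

    def test_er_is_odds_of_probability(self):
        rng = np.random.default_rng(3)
        w = rng.dirichlet(np.ones(4))
        summary = _stub_summary(w, [("A",), ("A", "B"), ("B",), ("C",)])
        imp = adjusted_importance(summary, ["A", "B", "C"])
        for _, r in imp.iterrows():
            p = r["adj_probability"]
            if p < 1:
                assert r["adj_er"] == pytest.approx(p / (1 - p), rel=1e-12)

    def test_rank_order_and_ties(self):
        summary = _stub_summary(
            [0.25, 0.25, 0.25, 0.25], [("B",), ("A",), ("A", "B"), ()]
        )
        imp = adjusted_importance(summary, ["A", "B"])
        # symmetric set: identical p and raw sums -> alphabetical tiebreak
        assert list(imp["covariate"]) == ["A", "B"]
        assert list(imp["rank"]) == [1, 2]


class TestFitModelSet:
    def test_weights_sum_to_one_and_single_zero_delta(
        self, small_records, small_panel
    ):
        tbl = assembly.build_joint_table(
            small_records, small_panel, ["tmin_breeding", "corvid"]
        )
        specs = enumerate_models(["tmin_breeding", "corvid"], max_effects=2)
        summary = fit_model_set(tbl, specs, candidates=["tmin_breeding", "corvid"])
        assert summary.models["weight"].sum() == pytest.approx(1.0, abs=1e-12)
        assert (summary.models["delta"] >= 0).all()
        assert (summary.models["delta"] == 0).sum() >= 1
        # the generating covariates should dominate the set
        imp = adjusted_importance(summary).set_index("covariate")
        assert imp.loc["tmin_breeding", "adj_probability"] > 0.9

    def test_missing_covariate_fails_before_fitting(self, small_records, small_panel):
        tbl = assembly.build_joint_table(small_records, small_panel, ["corvid"])
        specs = enumerate_models(["nonexistent"], max_effects=1)
        with pytest.raises(Exception, match="nonexistent"):
            fit_model_set(tbl, specs)


class TestVariableReduction:
    def test_strong_covariate_carried_forward(self):
        # known climate signal: carried forward in >=95% of seeded replicates
        design = synth.SurveyDesign(
            n_regions=2,
            counties_per_region=4,
            year_span={s: (1990, 2013) for s in synth.SURVEY_TYPES},
            coverage={s: 1.0 for s in synth.SURVEY_TYPES},
        )
        carried = 0
        n_rep = 20
        for seed in range(n_rep):
            truth = synth.SimTruth(
                beta_true={"tmin_breeding": 0.25},
                sigma_region=0.2,
                sigma_county=0.3,
                sigma_resid=0.05,
                q_survey={"AGTS": 4.0, "BBS": 1.0, "CBC": 2.0},
                intercept=2.5,
                dispersion=10.0,
                seed=seed,
            )
            panel = synth.generate_covariate_panel(design, seed)
            latent = synth.generate_latent_abundance(panel, truth)
            records = synth.generate_surveys(latent, truth, design)
            res = variable_reduction(
                records, panel, {"climate": ["tmin_breeding", "precip_winter"]}
            )
            if "tmin_breeding" in res["carried_forward"]:
                carried += 1
        assert carried >= 0.95 * n_rep

    def test_no_signal_group_contributes_nothing(self):
        # pure-noise abundance: no candidate model beats the baseline by 2
        # AICc units on this fixed-seed dataset, so nothing is carried
        design = synth.SurveyDesign(
            n_regions=2,
            counties_per_region=4,
            year_span={s: (1990, 2013) for s in synth.SURVEY_TYPES},
            coverage={s: 1.0 for s in synth.SURVEY_TYPES},
        )
        truth = synth.SimTruth(
            beta_true={}, sigma_region=0.2, sigma_county=0.3, sigma_resid=0.1,
            q_survey={"AGTS": 4.0, "BBS": 1.0, "CBC": 2.0},
            intercept=2.5, dispersion=10.0, seed=100,
        )
        panel = synth.generate_covariate_panel(design, 100)
        latent = synth.generate_latent_abundance(panel, truth)
        records = synth.generate_surveys(latent, truth, design)
        res = variable_reduction(
            records, panel, {"climate": ["precip_winter", "tmin_brood"]}
        )
        group = res["groups"]["climate"]
        assert not group["supported"].any()
        assert res["carried_forward"] == []

    def test_carried_terms_match_supported_flags(self, small_records, small_panel):
        res = variable_reduction(
            small_records,
            small_panel,
            {"climate": ["tmin_breeding", "precip_winter"], "avian": ["corvid"]},
        )
        supported = [
            row["candidate"]
            for df in res["groups"].values()
            for _, row in df.iterrows()
            if row["supported"]
        ]
        assert res["carried_forward"] == supported

    def test_interaction_can_pass_when_main_alone_fails(self):
        # effect exists only as covariate-by-year interaction
        design = synth.SurveyDesign(
            n_regions=2,
            counties_per_region=4,
            year_span={s: (1980, 2013) for s in synth.SURVEY_TYPES},
            coverage={s: 1.0 for s in synth.SURVEY_TYPES},
        )
        truth = synth.SimTruth(
            beta_true={"tmin_breeding:year": 0.02},
            sigma_region=0.2,
            sigma_county=0.3,
            sigma_resid=0.05,
            q_survey={"AGTS": 4.0, "BBS": 1.0, "CBC": 2.0},
            intercept=2.5,
            dispersion=10.0,
            seed=11,
        )
        panel = synth.generate_covariate_panel(design, 11)
        latent = synth.generate_latent_abundance(panel, truth)
        records = synth.generate_surveys(latent, truth, design)
        res = variable_reduction(
            records,
            panel,
            {"climate": ["tmin_breeding", "tmin_breeding:year"]},
        )
        assert "tmin_breeding:year" in res["carried_forward"]

    def test_empty_group_warns_and_skips(self, small_records, small_panel):
        with pytest.warns(UserWarning, match="no candidates"):
            res = variable_reduction(small_records, small_panel, {"empty": []})
        assert res["groups"] == {}
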