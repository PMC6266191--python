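"""Tie-rule and characteristic-rule semantics, parsing, and explanations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rosterlens import (
    PRESET_CHARACTERISTIC_RULES,
    RuleError,
    TieRule,
    classify_individual,
    evaluate_tie,
    load_rules_file,
    parse_characteristic_rule,
    parse_tie_rule,
)
from .conftest import make_individual

STRONG = TieRule("strong", require_reciprocity=True, min_each_weight=4)


class TestEvaluateTie:
    @pytest.mark.parametrize(
        "w_ab, w_ba, expected",
        [(4, 5, True), (5, 5, True), (4, 4, True), (4, 3, False), (5, None, False), (None, None, False)],
    )
    def test_strong_rule_verdicts(self, w_ab, w_ba, expected):
        verdict, expl = evaluate_tie(STRONG, w_ab, w_ba)
        assert verdict is expected
        assert expl.verdict is expected

    def test_failed_threshold_is_visible_in_explanation(self):
        _, expl = evaluate_tie(STRONG, 4, 3)
        failed = [r for r in expl.records if not r.satisfied]
        assert len(failed) == 1
        assert "each weight >= 4" in failed[0].condition
        assert failed[0].observed == (4, 3)

    def test_absent_weight_fails_reciprocity_not_thresholds(self):
        _, expl = evaluate_tie(STRONG, 5, None)
        failed = [r for r in expl.records if not r.satisfied]
        assert any("reciprocity" in r.condition for r in failed)

    def test_sum_and_mean_conditions_are_conjunctive(self):
        rule = TieRule("both", require_reciprocity=True, min_sum_weight=7, min_mean_weight=4)
        assert evaluate_tie(rule, 4, 4)[0] is True  # sum 8 >= 7, mean 4 >= 4
        assert evaluate_tie(rule, 5, 2)[0] is False  # sum 7 ok, mean 3.5 fails
        assert evaluate_tie(rule, 3, 3)[0] is False  # both fail

    def test_non_reciprocal_rule_accepts_one_direction(self):
        rule = TieRule("oneway", require_reciprocity=False, min_each_weight=3)
        assert evaluate_tie(rule, 4, None)[0] is True
        assert evaluate_tie(rule, 2, None)[0] is False
        assert evaluate_tie(rule, None, None)[0] is False

    @given(
        w_ab=st.one_of(st.none(), st.integers(1, 5)),
        w_ba=st.one_of(st.none(), st.integers(1, 5)),
        seed=st.integers(0, 10**6),
    )
    @settings(max_examples=200, deadline=None)
    def test_symmetry_and_explanation_replay(self, w_ab, w_ba, seed):
        from .conftest import random_tie_rule

        rule = random_tie_rule(np.random.default_rng(seed))
        v1, e1 = evaluate_tie(rule, w_ab, w_ba)
        v2, e2 = evaluate_tie(rule, w_ba, w_ab)
        assert v1 == v2  # both-link conditions are order-free
        assert e1.replay() == v1 and e2.replay() == v2

    @given(
        w_ab=st.integers(1, 5), w_ba=st.integers(1, 5),
        t1=st.integers(1, 5), t2=st.integers(1, 5),
    )
    @settings(max_examples=200, deadline=None)
    def test_threshold_monotonicity(self, w_ab, w_ba, t1, t2):
        t1, t2 = min(t1, t2), max(t1, t2)
        lax = TieRule("lax", require_reciprocity=True, min_each_weight=t1)
        strict = TieRule("strict", require_reciprocity=True, min_each_weight=t2)
        if evaluate_tie(strict, w_ab, w_ba)[0]:
            assert evaluate_tie(lax, w_ab, w_ba)[0]


class TestTieRuleParsing:
    def test_strong_relationship_fragment(self):
        rule = parse_tie_rule({"name": "strong", "reciprocity": True, "min_each_weight": 4})
        assert rule == TieRule("strong", require_reciprocity=True, min_each_weight=4)

    def test_weight_gt1_family_member(self):
        # ">1" on an integer 1-5 scale is "each weight >= 2"
        rule = parse_tie_rule({"name": "any", "reciprocity": True, "min_each_weight": 2})
        assert evaluate_tie(rule, 2, 2)[0] and not evaluate_tie(rule, 2, 1)[0]

    @pytest.mark.parametrize(
        "fragment, match",
        [
            ({"name": "bad"}, "empty rule"),
            ({"name": "bad", "min_each_weight": 4, "bogus": 1}, "unknown key"),
            ({"name": "bad", "min_mean_weight": 5.5}, "min_mean_weight"),
            ({"name": "bad", "min_each_weight": "4"}, "integer"),
            ({"min_each_weight": 4}, "missing 'name'"),
        ],
    )
    def test_malformed_fragments_rejected(self, fragment, match):
        with pytest.raises(RuleError, match=match):
            parse_tie_rule(fragment)


FINNISH = PRESET_CHARACTERISTIC_RULES["binge_drinker_finnish"]
SPANISH = PRESET_CHARACTERISTIC_RULES["binge_drinker_spanish"]


def _with_audit_c(score: int, gender: str):
    items = [0] * 10
    for i in range(3):
        items[i] = min(4, max(0, score - 4 * i))
    assert sum(items[:3]) == score
    return make_individual(gender=gender, audit=tuple(items))


class TestClassification:
    @pytest.mark.parametrize(
        "rule, gender, score, expected",
        [
            (FINNISH, "male", 8, True),
            (FINNISH, "male", 7, False),   # boundary of "greater than 7"
            (FINNISH, "female", 5, True),
            (FINNISH, "female", 4, False),
            (SPANISH, "female", 5, True),
            (SPANISH, "male", 5, True),
            (SPANISH, "male", 4, False),
        ],
    )
    def test_binge_drinker_presets(self, rule, gender, score, expected):
        verdict, expl = classify_individual(rule, _with_audit_c(score, gender))
        assert verdict is expected
        assert expl.replay() is expected

    def test_gender_scope_restricts_applicability(self):
        # a male never triggers the female clause even with a high score
        verdict, expl = classify_individual(FINNISH, _with_audit_c(6, "male"))
        assert verdict is False
        female_clause = [r for r in expl.records if r.clause_index == 1]
        assert all(r.condition == "gender_scope" for r in female_clause)

    def test_metric_condition_reads_supplied_metrics(self):
        popular = PRESET_CHARACTERISTIC_RULES["popular"]
        ind = make_individual()
        assert classify_individual(popular, ind, {"in_degree": 4})[0] is True
        assert classify_individual(popular, ind, {"in_degree": 3})[0] is False

    def test_unresolvable_score_source_names_it(self):
        from rosterlens import EvaluationError

        popular = PRESET_CHARACTERISTIC_RULES["popular"]
        with pytest.raises(EvaluationError, match="in_degree"):
            classify_individual(popular, make_individual(), {})
        rule = parse_characteristic_rule(
            {"name": "rich", "clauses": [[{"score": "extra_attribute:fas", "comparator": "ge", "threshold": 10}]]}
        )
        with pytest.raises(EvaluationError, match="fas"):
            classify_individual(rule, make_individual())

    def test_multi_condition_clause_is_conjunctive(self):
        bad = PRESET_CHARACTERISTIC_RULES["bad_influence"]
        heavy = _with_audit_c(9, "male")
        assert classify_individual(bad, heavy, {"degree": 5})[0] is True
        assert classify_individual(bad, heavy, {"degree": 2})[0] is False
        sober = _with_audit_c(2, "male")
        assert classify_individual(bad, sober, {"degree": 9})[0] is False


class TestCharacteristicParsing:
    def test_finnish_config_builds_two_clauses(self):
        rule = parse_characteristic_rule(
            {
                "name": "binge",
                "clauses": [
                    [{"score": "audit_c", "comparator": "gt", "threshold": 7, "gender": "male"}],
                    [{"score": "audit_c", "comparator": "gt", "threshold": 4, "gender": "female"}],
                ],
            }
        )
        assert len(rule.clauses) == 2
        assert rule.clauses[0][0].gender_scope == "male"

    @pytest.mark.parametrize(
        "fragment, match",
        [
            ({"name": "x", "clauses": [[{"score": "shoe_size", "comparator": "gt", "threshold": 1}]]},
             "unknown score_source"),
            ({"name": "x", "clauses": [[{"score": "audit_c", "comparator": "between", "threshold": 1}]]},
             "comparator"),
            ({"name": "x", "clauses": [[{"score": "audit_c", "comparator": "gt", "threshold": 1, "extra": 2}]]},
             "unknown key"),
            ({"name": "x", "clauses": []}, "clauses"),
            ({"name": "x"}, "needs 'name' and 'clauses'"),
        ],
    )
    def test_malformed_fragments_rejected(self, fragment, match):
        with pytest.raises(RuleError, match=match):
            parse_characteristic_rule(fragment)


@pytest.mark.parametrize("source, hi", [("audit_total", 40), ("audit_c", 12)])
def test_gt_k_equals_ge_k_plus_1_on_integer_scores(source, hi):
    """On integer scores, 'greater than k' and 'at least k+1' classify identically."""
    for k in range(0, hi):
        rule_gt = parse_characteristic_rule(
            {"name": "g", "clauses": [[{"score": source, "comparator": "gt", "threshold": k}]]}
        )
        rule_ge = parse_characteristic_rule(
            {"name": "g2", "clauses": [[{"score": source, "comparator": "ge", "threshold": k + 1}]]}
        )
        for score in (0, k, k + 1, hi):
            ind = (
                _with_audit_c(min(score, 12), "male")
                if source == "audit_c"
                else make_individual(audit=_items_with_total(score))
            )
            if source == "audit_total":
                assert classify_individual(rule_gt, ind)[0] == classify_individual(rule_ge, ind)[0]
            elif score <= 12:
                assert classify_individual(rule_gt, ind)[0] == classify_individual(rule_ge, ind)[0]


def _items_with_total(total: int):
    # items 9-10 can only absorb even amounts, so reserve an even tail first
    tail = max(0, total - 32)
    tail += tail % 2
    items = [0] * 10
    items[8] = min(4, tail)
    items[9] = tail - items[8]
    remaining = total - tail
    for i in range(8):
        items[i] = min(4, remaining)
        remaining -= items[i]
    assert remaining == 0 and sum(items) == total
    return tuple(items)


def test_load_rules_file_with_presets_and_inline_rules():
    doc = {
        "tie_rules": [
            {"preset": "strong_friendship"},
            {"name": "mean3", "reciprocity": True, "min_mean_weight": 3},
        ],
        "characteristic_rules": [{"preset": "binge_drinker_spanish"}],
    }
    ties, chars = load_rules_file(doc)
    assert set(ties) == {"strong_friendship", "mean3"}
    assert set(chars) == {"binge_drinker_spanish"}
    with pytest.raises(RuleError, match="duplicate"):
        load_rules_file({"tie_rules": [{"preset": "contact"}, {"preset": "contact"}]})
    with pytest.raises(RuleError, match="unknown key"):
        load_rules_file({"tie_ruless": []})
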