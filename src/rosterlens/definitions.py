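"""Declarative tie and characteristic definitions with explanation traces.

The scientific point of this package is that "friendship" and "binge
drinker" have no single operational definition: a tie rule says when a
roster dyad counts as a tie (reciprocity, per-direction minimum weight,
minimum sum, minimum mean — all conjunctive), and a characteristic rule says
when a derived label (binge_drinker, popular, bad_influence, ...) applies to
an individual as an OR-of-ANDs over score conditions that may be
gender-scoped and may read network metrics.

Every verdict carries an :class:`Explanation`: the full record of each
condition evaluated, the observed value, the threshold, and whether it was
satisfied — so any derived edge or label can be audited after the fact.

Shipped presets cover the published definitions this package was built
around: the reciprocal contact-threshold family (weights > 1, > 2, > 3
"strong friendship", > 4 "best friends") and the competing binge-drinker
cut-offs on the AUDIT-C consumption score (Finnish gender-stratified:
> 7 for males, > 4 for females; Spanish uniform: > 4 for everyone).
"""

from __future__ import annotations

import operator
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping, Sequence

from .errors import EvaluationError, RuleError
from .questionnaire import GENDERS, Individual

COMPARATORS = {"ge": operator.ge, "gt": operator.gt, "le": operator.le, "lt": operator.lt}
_COMPARATOR_SYMBOL = {"ge": ">=", "gt": ">", "le": "<=", "lt": "<"}
OUTPUT_WEIGHTINGS = ("dichotomous", "min", "mean", "sum")


# ---------------------------------------------------------------------------
# explanations


@dataclass(frozen=True)
class ConditionRecord:
    """One evaluated condition: what was checked, what was seen, how it went."""

    condition: str
    observed: object
    threshold: object
    satisfied: bool
    clause_index: int = 0


@dataclass(frozen=True)
class Explanation:
    """Audit trail for a single tie or label verdict.

    ``structure`` is ``"conjunction"`` for tie rules (verdict = all records
    satisfied) or ``"dnf"`` for characteristic rules (verdict = some
    *applicable* clause has all its condition records satisfied; records with
    ``condition == "gender_scope"`` mark clause applicability).
    """

    subject: object
    rule_name: str
    records: tuple[ConditionRecord, ...]
    verdict: bool
    structure: str = "conjunction"

    def replay(self) -> bool:
        """Recompute the verdict from the recorded observations alone."""
        if self.structure == "conjunction":
            return all(r.satisfied for r in self.records)
        clauses: dict[int, list[ConditionRecord]] = {}
        for r in self.records:
            clauses.setdefault(r.clause_index, []).append(r)
        return any(all(r.satisfied for r in recs) for recs in clauses.values())

    def describe(self) -> str:
        lines = [f"{self.rule_name} on {self.subject}: {'YES' if self.verdict else 'no'}"]
        for r in self.records:
            mark = "ok" if r.satisfied else "FAIL"
            lines.append(
                f"  [clause {r.clause_index}] {r.condition}: observed={r.observed} "
                f"threshold={r.threshold} -> {mark}"
            )
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# tie rules


@dataclass(frozen=True)
class TieRule:
    """When does a roster dyad count as a tie?

    All set conditions are conjunctive. ``min_each_weight`` applies to every
    present direction; ``min_sum_weight`` / ``min_mean_weight`` apply to the
    sum / mean over present directions. With ``require_reciprocity`` both
    directions must have been named at all.
    """

    name: str
    require_reciprocity: bool = False
    min_each_weight: int | None = None
    min_sum_weight: int | None = None
    min_mean_weight: float | None = None
    output_weighting: str = "dichotomous"

    def __post_init__(self):
        if not self.name:
            raise RuleError("tie rule needs a non-empty name")
        if (
            self.min_each_weight is None
            and self.min_sum_weight is None
            and self.min_mean_weight is None
        ):
            raise RuleError(f"tie rule {self.name!r}: empty rule — no threshold condition set")
        if self.min_each_weight is not None and not 1 <= self.min_each_weight <= 5:
            raise RuleError(f"tie rule {self.name!r}: min_each_weight outside [1, 5]")
        if self.min_sum_weight is not None and not 2 <= self.min_sum_weight <= 10:
            raise RuleError(f"tie rule {self.name!r}: min_sum_weight outside [2, 10]")
        if self.min_mean_weight is not None and not 1 <= self.min_mean_weight <= 5:
            raise RuleError(f"tie rule {self.name!r}: min_mean_weight outside [1, 5]")
        if self.output_weighting not in OUTPUT_WEIGHTINGS:
            raise RuleError(
                f"tie rule {self.name!r}: output_weighting must be one of {OUTPUT_WEIGHTINGS}"
            )

    def edge_weight(self, weight_ab: int | None, weight_ba: int | None) -> float:
        """Weight carried by a derived edge under this rule's output_weighting."""
        present = [w for w in (weight_ab, weight_ba) if w is not None]
        if self.output_weighting == "dichotomous" or not present:
            return 1.0
        if self.output_weighting == "min":
            return float(min(present))
        if self.output_weighting == "sum":
            return float(sum(present))
        return sum(present) / len(present)


def evaluate_tie(
    rule: TieRule,
    weight_ab: int | None,
    weight_ba: int | None,
    subject: object = None,
) -> tuple[bool, Explanation]:
    """Evaluate one unordered dyad under a tie rule.

    ``weight_ab`` / ``weight_ba`` are the two directed roster weights, None if
    that direction was never answered. An absent weight under reciprocity
    yields verdict False (never an error). Returns the verdict together with
    its full explanation trace.
    """
    records: list[ConditionRecord] = []
    present = [w for w in (weight_ab, weight_ba) if w is not None]

    if rule.require_reciprocity:
        ok = weight_ab is not None and weight_ba is not None
        records.append(
            ConditionRecord(
                "reciprocity: both directions named",
                (weight_ab, weight_ba),
                "both present",
                ok,
            )
        )
    else:
        records.append(
            ConditionRecord(
                "at least one direction named", (weight_ab, weight_ba), "any present",
                bool(present),
            )
        )

    if rule.min_each_weight is not None:
        ok = bool(present) and all(w >= rule.min_each_weight for w in present)
        records.append(
            ConditionRecord(
                f"each weight >= {rule.min_each_weight}",
                (weight_ab, weight_ba),
                rule.min_each_weight,
                ok,
            )
        )
    if rule.min_sum_weight is not None:
        total = sum(present) if present else None
        records.append(
            ConditionRecord(
                f"weight sum >= {rule.min_sum_weight}", total, rule.min_sum_weight,
                total is not None and total >= rule.min_sum_weight,
            )
        )
    if rule.min_mean_weight is not None:
        mean = Fraction(sum(present), len(present)) if present else None
        records.append(
            ConditionRecord(
                f"weight mean >= {rule.min_mean_weight}",
                None if mean is None else float(mean),
                rule.min_mean_weight,
                mean is not None and mean >= Fraction(rule.min_mean_weight).limit_denominator(10**6),
            )
        )

    verdict = all(r.satisfied for r in records)
    return verdict, Explanation(
        subject=subject, rule_name=rule.name, records=tuple(records), verdict=verdict
    )


# ---------------------------------------------------------------------------
# characteristic rules

SCORE_SOURCES = ("audit_total", "audit_c")  # plus extra_attribute:<n>, sna_metric:<n>


@dataclass(frozen=True)
class ScoreCondition:
    """One threshold comparison on a score source.

    ``score_source`` is ``audit_total``, ``audit_c``, ``extra_attribute:<name>``
    or ``sna_metric:<name>``. ``gender_scope`` restricts which individuals the
    enclosing clause applies to; it never flips a truth value.
    """

    score_source: str
    comparator: str
    threshold: float
    gender_scope: str = "any"

    def __post_init__(self):
        src = self.score_source
        if src not in SCORE_SOURCES and not (
            src.startswith("extra_attribute:") or src.startswith("sna_metric:")
        ):
            raise RuleError(
                f"unknown score_source {src!r}; expected one of {SCORE_SOURCES} "
                "or 'extra_attribute:<name>' / 'sna_metric:<name>'"
            )
        if self.comparator not in COMPARATORS:
            raise RuleError(
                f"comparator must be one of {tuple(COMPARATORS)}, got {self.comparator!r}"
            )
        if not isinstance(self.threshold, (int, float)) or self.threshold != self.threshold:
            raise RuleError(f"threshold must be a finite number, got {self.threshold!r}")
        if self.gender_scope not in GENDERS + ("any",):
            raise RuleError(f"gender_scope must be male/female/any, got {self.gender_scope!r}")

    def resolve(self, individual: Individual, metrics: Mapping[str, float] | None) -> float:
        """Look up this condition's observed value for one individual."""
        src = self.score_source
        if src == "audit_total":
            return individual.audit_total
        if src == "audit_c":
            return individual.audit_c
        if src.startswith("extra_attribute:"):
            name = src.split(":", 1)[1]
            if name not in individual.extra_attributes:
                raise EvaluationError(
                    f"individual {individual.id!r} has no extra attribute {name!r}"
                )
            return float(individual.extra_attributes[name])
        name = src.split(":", 1)[1]
        if metrics is None or name not in metrics:
            raise EvaluationError(
                f"SNA metric {name!r} not available for individual {individual.id!r}"
            )
        return float(metrics[name])

    def describe(self) -> str:
        scope = "" if self.gender_scope == "any" else f" [{self.gender_scope}]"
        return f"{self.score_source} {_COMPARATOR_SYMBOL[self.comparator]} {self.threshold}{scope}"


@dataclass(frozen=True)
class CharacteristicRule:
    """A derived individual label as a disjunction of condition conjunctions.

    The label applies iff at least one clause (a) is applicable to the
    individual's gender (every condition's ``gender_scope`` matches) and
    (b) has all its conditions satisfied.
    """

    name: str
    clauses: tuple[tuple[ScoreCondition, ...], ...]

    def __post_init__(self):
        if not self.name:
            raise RuleError("characteristic rule needs a non-empty name")
        if not self.clauses or any(not c for c in self.clauses):
            raise RuleError(f"rule {self.name!r}: clauses must be non-empty")

    def clause_applies_to(self, gender: str, clause: Sequence[ScoreCondition]) -> bool:
        return all(c.gender_scope in ("any", gender) for c in clause)


def classify_individual(
    rule: CharacteristicRule,
    individual: Individual,
    metrics: Mapping[str, float] | None = None,
) -> tuple[bool, Explanation]:
    """Decide whether ``rule``'s label applies to ``individual``.

    ``metrics`` supplies the per-node SNA metric values for ``sna_metric:*``
    sources (typically the row of a scenario's metric table). Every evaluated
    clause is recorded in the explanation; inapplicable clauses are recorded
    as failed gender-scope checks.
    """
    records: list[ConditionRecord] = []
    verdict = False
    for ci, clause in enumerate(rule.clauses):
        applicable = rule.clause_applies_to(individual.gender, clause)
        scopes = sorted({c.gender_scope for c in clause if c.gender_scope != "any"})
        records.append(
            ConditionRecord(
                "gender_scope", individual.gender, scopes or ["any"], applicable, ci
            )
        )
        clause_ok = applicable
        for cond in clause:
            if not applicable:
                continue  # conditions of an inapplicable clause are not resolved
            observed = cond.resolve(individual, metrics)
            ok = COMPARATORS[cond.comparator](observed, cond.threshold)
            records.append(
                ConditionRecord(cond.describe(), observed, cond.threshold, ok, ci)
            )
            clause_ok = clause_ok and ok
        verdict = verdict or clause_ok
    return verdict, Explanation(
        subject=individual.id,
        rule_name=rule.name,
        records=tuple(records),
        verdict=verdict,
        structure="dnf",
    )


# ---------------------------------------------------------------------------
# config parsing (YAML/JSON fragments already loaded into dicts)

_TIE_KEYS = {
    "name",
    "reciprocity",
    "min_each_weight",
    "min_sum_weight",
    "min_mean_weight",
    "output_weighting",
}


def parse_tie_rule(fragment: Mapping) -> TieRule:
    """Build a :class:`TieRule` from a config mapping.

    Unknown keys are rejected, not ignored; a rule with no threshold
    condition is an "empty rule" error.
    """
    if not isinstance(fragment, Mapping):
        raise RuleError(f"tie rule fragment must be a mapping, got {type(fragment).__name__}")
    unknown = set(fragment) - _TIE_KEYS
    if unknown:
        raise RuleError(f"tie rule: unknown key(s) {sorted(unknown)}; allowed: {sorted(_TIE_KEYS)}")
    if "name" not in fragment:
        raise RuleError("tie rule fragment missing 'name'")
    return TieRule(
        name=str(fragment["name"]),
        require_reciprocity=bool(fragment.get("reciprocity", False)),
        min_each_weight=_opt_int(fragment, "min_each_weight"),
        min_sum_weight=_opt_int(fragment, "min_sum_weight"),
        min_mean_weight=_opt_num(fragment, "min_mean_weight"),
        output_weighting=str(fragment.get("output_weighting", "dichotomous")),
    )


def _opt_int(fragment: Mapping, key: str) -> int | None:
    val = fragment.get(key)
    if val is None:
        return None
    if not isinstance(val, int) or isinstance(val, bool):
        raise RuleError(f"{key} must be an integer, got {val!r}")
    return val


def _opt_num(fragment: Mapping, key: str) -> float | None:
    val = fragment.get(key)
    if val is None:
        return None
    if not isinstance(val, (int, float)) or isinstance(val, bool):
        raise RuleError(f"{key} must be a number, got {val!r}")
    return float(val)


_COND_KEYS = {"score", "comparator", "threshold", "gender"}


def _parse_condition(fragment: Mapping) -> ScoreCondition:
    if not isinstance(fragment, Mapping):
        raise RuleError(f"condition must be a mapping, got {type(fragment).__name__}")
    unknown = set(fragment) - _COND_KEYS
    if unknown:
        raise RuleError(f"condition: unknown key(s) {sorted(unknown)}; allowed: {sorted(_COND_KEYS)}")
    for key in ("score", "comparator", "threshold"):
        if key not in fragment:
            raise RuleError(f"condition missing required key {key!r}")
    return ScoreCondition(
        score_source=str(fragment["score"]),
        comparator=str(fragment["comparator"]),
        threshold=fragment["threshold"],
        gender_scope=str(fragment.get("gender", "any")),
    )


_CHAR_KEYS = {"name", "clauses"}


def parse_characteristic_rule(fragment: Mapping) -> CharacteristicRule:
    """Build a :class:`CharacteristicRule` from a config mapping.

    ``clauses`` is a list of clauses; each clause is a list of condition
    mappings (a bare condition mapping is accepted as a one-condition
    clause). Richer boolean nesting is rejected at parse time.
    """
    if not isinstance(fragment, Mapping):
        raise RuleError(
            f"characteristic rule fragment must be a mapping, got {type(fragment).__name__}"
        )
    unknown = set(fragment) - _CHAR_KEYS
    if unknown:
        raise RuleError(f"characteristic rule: unknown key(s) {sorted(unknown)}")
    if "name" not in fragment or "clauses" not in fragment:
        raise RuleError("characteristic rule fragment needs 'name' and 'clauses'")
    raw_clauses = fragment["clauses"]
    if not isinstance(raw_clauses, Sequence) or isinstance(raw_clauses, (str, bytes)):
        raise RuleError("'clauses' must be a list")
    clauses = []
    for raw in raw_clauses:
        if isinstance(raw, Mapping):
            raw = [raw]
        if not isinstance(raw, Sequence):
            raise RuleError("each clause must be a list of conditions (or one condition)")
        clauses.append(tuple(_parse_condition(c) for c in raw))
    return CharacteristicRule(name=str(fragment["name"]), clauses=tuple(clauses))


# ---------------------------------------------------------------------------
# presets: the published definitions this package was built to compare


def _cond(score, comparator, threshold, gender="any"):
    return ScoreCondition(score, comparator, threshold, gender)


#: Reciprocal contact-threshold family: ties need mutual mentions with both
#: weights above 1 / 2 / 3 / 4 on the 1-5 roster scale.
PRESET_TIE_RULES: dict[str, TieRule] = {
    r.name: r
    for r in (
        TieRule("contact", require_reciprocity=True, min_each_weight=2),
        TieRule("friendship", require_reciprocity=True, min_each_weight=3),
        TieRule("strong_friendship", require_reciprocity=True, min_each_weight=4),
        TieRule("best_friends", require_reciprocity=True, min_each_weight=5),
    )
}

#: Competing binge-drinker cut-offs on the AUDIT-C consumption score, plus
#: comparator variants reflecting how ambiguously the cut-offs are published.
PRESET_CHARACTERISTIC_RULES: dict[str, CharacteristicRule] = {
    r.name: r
    for r in (
        # Finnish, gender-stratified: > 7 males (== >= 8), > 4 females (== >= 5)
        CharacteristicRule(
            "binge_drinker_finnish",
            ((_cond("audit_c", "gt", 7, "male"),), (_cond("audit_c", "gt", 4, "female"),)),
        ),
        # variant reading "7 or 8" as >= 7 for males
        CharacteristicRule(
            "binge_drinker_finnish_ge7",
            ((_cond("audit_c", "ge", 7, "male"),), (_cond("audit_c", "gt", 4, "female"),)),
        ),
        # Spanish, uniform: > 4 regardless of gender
        CharacteristicRule("binge_drinker_spanish", ((_cond("audit_c", "gt", 4),),)),
        # variant reading "best cut-off point ... 4" as >= 4
        CharacteristicRule("binge_drinker_spanish_ge4", ((_cond("audit_c", "ge", 4),),)),
        # named by four or more peers on the scenario's network
        CharacteristicRule("popular", ((_cond("sna_metric:in_degree", "ge", 4),),)),
    )
}

#: A binge drinker with many ties on the scenario's network.
PRESET_CHARACTERISTIC_RULES["bad_influence"] = CharacteristicRule(
    "bad_influence",
    (
        (
            _cond("audit_c", "gt", 7, "male"),
            _cond("sna_metric:degree", "ge", 4, "male"),
        ),
        (
            _cond("audit_c", "gt", 4, "female"),
            _cond("sna_metric:degree", "ge", 4, "female"),
        ),
    ),
)


def load_rules_file(fragment: Mapping) -> tuple[dict[str, TieRule], dict[str, CharacteristicRule]]:
    """Parse a loaded rules document: ``{tie_rules: [...], characteristic_rules: [...]}``.

    Preset names may be pulled in with ``{preset: <name>}`` entries in either
    list. Unknown top-level keys and duplicate rule names are errors.
    """
    allowed = {"tie_rules", "characteristic_rules"}
    if not isinstance(fragment, Mapping):
        raise RuleError("rules document must be a mapping")
    unknown = set(fragment) - allowed
    if unknown:
        raise RuleError(f"rules document: unknown key(s) {sorted(unknown)}")
    tie_rules: dict[str, TieRule] = {}
    char_rules: dict[str, CharacteristicRule] = {}
    for raw in fragment.get("tie_rules", []) or []:
        rule = _maybe_preset(raw, PRESET_TIE_RULES) or parse_tie_rule(raw)
        if rule.name in tie_rules:
            raise RuleError(f"duplicate tie rule name {rule.name!r}")
        tie_rules[rule.name] = rule
    for raw in fragment.get("characteristic_rules", []) or []:
        rule = _maybe_preset(raw, PRESET_CHARACTERISTIC_RULES) or parse_characteristic_rule(raw)
        if rule.name in char_rules:
            raise RuleError(f"duplicate characteristic rule name {rule.name!r}")
        char_rules[rule.name] = rule
    return tie_rules, char_rules


def _maybe_preset(raw, presets):
    if isinstance(raw, Mapping) and set(raw) == {"preset"}:
        name = raw["preset"]
        if name not in presets:
            raise RuleError(f"unknown preset {name!r}; available: {sorted(presets)}")
        return presets[name]
    return None
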