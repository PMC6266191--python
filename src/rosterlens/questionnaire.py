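"""Roster-questionnaire data model and AUDIT scoring.

A roster study collects, for every participant, (a) individual attributes
including the 10-item Alcohol Use Disorders Identification Test (AUDIT) and
(b) a rating of the time spent with every classmate on a 1-5 contact scale
(1 = "We never spend time together" ... 5 = "We are always together").

This module holds the validated in-memory containers (:class:`Individual`,
:class:`DyadRating`, :class:`ResponseSet`), the AUDIT / AUDIT-C scoring
functions, the mapping from printed AUDIT response texts to item scores, and
delimited-text readers/writers with row-level diagnostics.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import SchemaError, ValidationError

logger = logging.getLogger(__name__)

GENDERS = ("male", "female")

#: Legal scores per AUDIT item: items 1-8 are scored 0..4, items 9-10 are
#: printed with only three response options scored 0, 2 or 4.
AUDIT_ITEM_VALUES: tuple[frozenset[int], ...] = tuple(
    frozenset({0, 1, 2, 3, 4}) if i < 8 else frozenset({0, 2, 4}) for i in range(10)
)

MIN_WEIGHT, MAX_WEIGHT = 1, 5

_FREQ_OPTIONS = (
    "Never",
    "Less than monthly",
    "Monthly",
    "Weekly",
    "Daily or almost daily",
)

#: Printed response options per AUDIT question, as (text, score) pairs.
AUDIT_RESPONSE_OPTIONS: dict[int, tuple[tuple[str, int], ...]] = {
    1: (
        ("Never", 0),
        ("Monthly or less", 1),
        ("2-4 times a month", 2),
        ("2-3 times a week", 3),
        ("4 or more times a week", 4),
    ),
    2: (("0-2", 0), ("3 or 4", 1), ("5 or 6", 2), ("7-9", 3), ("10 or more", 4)),
    **{q: tuple(zip(_FREQ_OPTIONS, range(5))) for q in range(3, 9)},
    9: (("No", 0), ("Yes, but not in the last year", 2), ("Yes, in the last year", 4)),
    10: (("No", 0), ("Yes, but not in the last year", 2), ("Yes, in the last year", 4)),
}


def _canon(text: str) -> str:
    # tolerate en-dashes and spacing variants in transcribed option texts
    return " ".join(text.replace("–", "-").replace("—", "-").split()).lower()


def validate_audit_items(items: Sequence[int]) -> tuple[int, ...]:
    """Check an AUDIT item vector and return it as a tuple of ints.

    Raises :class:`ValidationError` on wrong length or out-of-range items
    (items 9-10 only admit 0, 2 or 4).
    """
    items = tuple(int(x) for x in items)
    if len(items) != 10:
        raise ValidationError(f"AUDIT requires exactly 10 item scores, got {len(items)}")
    for i, (val, legal) in enumerate(zip(items, AUDIT_ITEM_VALUES), start=1):
        if val not in legal:
            raise ValidationError(
                f"AUDIT item {i} score {val} not in {sorted(legal)}"
            )
    return items


def score_audit(items: Sequence[int]) -> int:
    """Total AUDIT score: the sum of all 10 item scores, in [0, 40]."""
    return sum(validate_audit_items(items))


def score_audit_c(items: Sequence[int]) -> int:
    """AUDIT-C consumption subscore: the sum of items 1-3 only, in [0, 12]."""
    return sum(validate_audit_items(items)[:3])


def map_audit_response_text(question_index: int, response_text: str) -> int:
    """Map a printed AUDIT response option to its item score.

    ``question_index`` is 1-based. Unknown texts raise :class:`ValidationError`
    listing the valid options for that question.
    """
    if question_index not in AUDIT_RESPONSE_OPTIONS:
        raise ValidationError(f"AUDIT question index must be 1-10, got {question_index}")
    options = AUDIT_RESPONSE_OPTIONS[question_index]
    wanted = _canon(response_text)
    for text, score in options:
        if _canon(text) == wanted:
            return score
    valid = ", ".join(repr(t) for t, _ in options)
    raise ValidationError(
        f"unknown response {response_text!r} for AUDIT question {question_index}; "
        f"valid options: {valid}"
    )


@dataclass(frozen=True)
class Individual:
    """One study participant.

    ``audit_items`` holds the already-scored 10 AUDIT item values (or None if
    the instrument was not administered); other instrument totals (FAS II,
    KIDSCREEN-27, ...) travel as precomputed numbers in ``extra_attributes``.
    """

    id: str
    classroom_id: str
    gender: str
    audit_items: tuple[int, ...] | None = None
    extra_attributes: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.gender not in GENDERS:
            raise ValidationError(
                f"individual {self.id!r}: gender must be one of {GENDERS}, got {self.gender!r}"
            )
        if self.audit_items is not None:
            object.__setattr__(self, "audit_items", validate_audit_items(self.audit_items))

    @property
    def audit_total(self) -> int:
        if self.audit_items is None:
            raise ValidationError(f"individual {self.id!r} has no AUDIT responses")
        return sum(self.audit_items)

    @property
    def audit_c(self) -> int:
        if self.audit_items is None:
            raise ValidationError(f"individual {self.id!r} has no AUDIT responses")
        return sum(self.audit_items[:3])


@dataclass(frozen=True)
class DyadRating:
    """One directed roster rating: ``rater`` spends ``weight`` (1-5) time with ``ratee``."""

    rater: str
    ratee: str
    weight: int

    def __post_init__(self):
        if self.rater == self.ratee:
            raise ValidationError(f"self-rating: {self.rater!r} rated themselves")
        if not (MIN_WEIGHT <= int(self.weight) <= MAX_WEIGHT):
            raise ValidationError(
                f"rating {self.rater!r}->{self.ratee!r}: weight {self.weight} outside "
                f"{MIN_WEIGHT}-{MAX_WEIGHT}"
            )
        object.__setattr__(self, "weight", int(self.weight))


class ResponseSet:
    """A validated study: individuals plus their ordered dyad ratings.

    At most one rating per ordered (rater, ratee) pair; every endpoint must be
    a known individual; ratings must stay within a classroom unless
    ``allow_cross_classroom`` is set.
    """

    def __init__(
        self,
        individuals: Iterable[Individual],
        ratings: Iterable[DyadRating],
        metadata: Mapping[str, str] | None = None,
        allow_cross_classroom: bool = False,
    ):
        self.individuals: dict[str, Individual] = {}
        for ind in individuals:
            if ind.id in self.individuals:
                raise ValidationError(f"duplicate individual id {ind.id!r}")
            self.individuals[ind.id] = ind
        self.ratings: dict[tuple[str, str], DyadRating] = {}
        for r in ratings:
            key = (r.rater, r.ratee)
            if key in self.ratings:
                raise ValidationError(f"duplicate rating for pair {key}")
            for endpoint in key:
                if endpoint not in self.individuals:
                    raise ValidationError(f"rating references unknown individual {endpoint!r}")
            if (
                not allow_cross_classroom
                and self.individuals[r.rater].classroom_id
                != self.individuals[r.ratee].classroom_id
            ):
                raise ValidationError(
                    f"cross-classroom rating {key} (set allow_cross_classroom to permit)"
                )
            self.ratings[key] = r
        self.metadata = dict(metadata or {})
        self.allow_cross_classroom = allow_cross_classroom

    @property
    def classrooms(self) -> list[str]:
        return sorted({ind.classroom_id for ind in self.individuals.values()})

    def rating_weight(self, rater: str, ratee: str) -> int | None:
        """The recorded weight for an ordered pair, or None if unanswered."""
        r = self.ratings.get((rater, ratee))
        return None if r is None else r.weight

    def classroom_members(self, classroom_id: str) -> list[Individual]:
        return [i for i in self.individuals.values() if i.classroom_id == classroom_id]

    def __eq__(self, other) -> bool:
        if not isinstance(other, ResponseSet):
            return NotImplemented
        # metadata is descriptive, not part of the study's identity
        return self.individuals == other.individuals and self.ratings == other.ratings

    def __repr__(self) -> str:
        return (
            f"ResponseSet({len(self.individuals)} individuals, "
            f"{len(self.ratings)} ratings, {len(self.classrooms)} classrooms)"
        )


# ---------------------------------------------------------------------------
# tabular I/O

_INDIVIDUAL_REQUIRED = ["id", "classroom_id", "gender"]
_AUDIT_COLS = [f"audit_q{i}" for i in range(1, 11)]
_RATING_REQUIRED = ["rater_id", "ratee_id", "weight"]


def _sniff_delimiter(path: Path) -> str:
    with open(path, newline="", encoding="utf-8") as fh:
        header = fh.readline()
    try:
        return csv.Sniffer().sniff(header, delimiters=",;\t").delimiter
    except csv.Error:
        return ","


def _read_table(path: Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"file not found: {path}")
    df = pd.read_csv(path, sep=_sniff_delimiter(path), dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    return df


def read_response_set(
    individuals_path: str | Path,
    ratings_path: str | Path,
    allow_cross_classroom: bool = False,
) -> ResponseSet:
    """Read and validate a study from an individuals table and a ratings table.

    Expected columns (header row; delimiter auto-detected among comma,
    semicolon and tab):

    * individuals: ``id, classroom_id, gender[, audit_q1..audit_q10, <extras>]``
    * ratings (edge list): ``rater_id, ratee_id, weight``

    Every malformed row is collected and reported with its row number; any
    error raises :class:`ValidationError` (or :class:`SchemaError` for
    missing columns).
    """
    ind_df = _read_table(Path(individuals_path), _INDIVIDUAL_REQUIRED)
    rat_df = _read_table(Path(ratings_path), _RATING_REQUIRED)

    has_audit = all(c in ind_df.columns for c in _AUDIT_COLS)
    extra_cols = [
        c for c in ind_df.columns if c not in _INDIVIDUAL_REQUIRED + _AUDIT_COLS
    ]

    errors: list[tuple[int, str]] = []
    individuals: list[Individual] = []
    for idx, row in ind_df.iterrows():
        rowno = int(idx) + 2  # 1-based, after header
        try:
            audit = None
            if has_audit and all(str(row[c]).strip() != "" for c in _AUDIT_COLS):
                audit = tuple(int(row[c]) for c in _AUDIT_COLS)
            extras = {}
            for c in extra_cols:
                val = str(row[c]).strip()
                if val != "":
                    try:
                        # preserve integer-valued extras exactly across round-trips
                        extras[c] = int(val)
                    except ValueError:
                        try:
                            extras[c] = float(val)
                        except ValueError:
                            extras[c] = val
            individuals.append(
                Individual(
                    id=str(row["id"]).strip(),
                    classroom_id=str(row["classroom_id"]).strip(),
                    gender=str(row["gender"]).strip().lower(),
                    audit_items=audit,
                    extra_attributes=extras,
                )
            )
        except (ValidationError, ValueError) as exc:
            errors.append((rowno, str(exc)))
    if errors:
        raise ValidationError(f"{individuals_path}: invalid individual rows", errors)

    ratings: list[DyadRating] = []
    for idx, row in rat_df.iterrows():
        rowno = int(idx) + 2
        try:
            ratings.append(
                DyadRating(
                    rater=str(row["rater_id"]).strip(),
                    ratee=str(row["ratee_id"]).strip(),
                    weight=int(row["weight"]),
                )
            )
        except (ValidationError, ValueError) as exc:
            errors.append((rowno, str(exc)))
    if errors:
        raise ValidationError(f"{ratings_path}: invalid rating rows", errors)

    try:
        return ResponseSet(
            individuals, ratings, allow_cross_classroom=allow_cross_classroom
        )
    except ValidationError:
        raise


def write_response_set(
    responses: ResponseSet,
    individuals_path: str | Path,
    ratings_path: str | Path,
) -> None:
    """Write a study back to the two delimited files ``read_response_set`` reads.

    Output is deterministic (sorted by id / ordered pair) so identical studies
    produce byte-identical files.
    """
    extra_cols = sorted(
        {k for ind in responses.individuals.values() for k in ind.extra_attributes}
    )
    has_audit = any(i.audit_items is not None for i in responses.individuals.values())
    cols = _INDIVIDUAL_REQUIRED + (_AUDIT_COLS if has_audit else []) + extra_cols
    rows = []
    for ind in sorted(responses.individuals.values(), key=lambda i: i.id):
        row: dict[str, object] = {
            "id": ind.id,
            "classroom_id": ind.classroom_id,
            "gender": ind.gender,
        }
        if has_audit:
            items = ind.audit_items or ("",) * 10
            row.update(dict(zip(_AUDIT_COLS, items)))
        for c in extra_cols:
            row[c] = ind.extra_attributes.get(c, "")
        rows.append(row)
    pd.DataFrame(rows, columns=cols).to_csv(individuals_path, index=False)

    rat_rows = [
        {"rater_id": r.rater, "ratee_id": r.ratee, "weight": r.weight}
        for r in (responses.ratings[k] for k in sorted(responses.ratings))
    ]
    pd.DataFrame(rat_rows, columns=_RATING_REQUIRED).to_csv(ratings_path, index=False)
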