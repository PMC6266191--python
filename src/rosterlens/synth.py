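"""Seeded generator of synthetic classroom studies.

Emulates the shape of a multi-classroom adolescent roster study: around nine
classrooms of 23-25 students each (~214 total), gendered nodes, a planted
group structure inside every classroom (friendship groups rate each other
high on the 1-5 contact scale, everyone else low), imperfectly reciprocal
ratings, and AUDIT responses whose drinking propensity mixes a group-level
component with an individual one — the ``drinking_homophily`` knob moves
drinking from purely individual (0) to purely group-determined (1), which is
what makes same-label clustering appear on the derived friendship networks.

The generated :class:`~rosterlens.questionnaire.ResponseSet` rates every
ordered within-classroom dyad exactly once and is fully reproducible from
the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .questionnaire import DyadRating, Individual, ResponseSet

WEIGHTS = np.arange(1, 6)

# Baseline per-item response distributions for a low-drinking adolescent
# population (items 1-8 over scores 0..4; items 9-10 over 0/2/4), and the
# "heavy" counterparts a high-propensity individual is pulled towards.
_BASE_Q13 = (0.45, 0.30, 0.15, 0.07, 0.03)
_HEAVY_Q13 = (0.05, 0.15, 0.30, 0.30, 0.20)
_BASE_Q48 = (0.80, 0.12, 0.05, 0.02, 0.01)
_HEAVY_Q48 = (0.35, 0.30, 0.20, 0.10, 0.05)
_BASE_Q910 = (0.90, 0.07, 0.03)
_HEAVY_Q910 = (0.55, 0.30, 0.15)

DEFAULT_BASE_ITEMS: tuple[tuple[float, ...], ...] = (_BASE_Q13,) * 3 + (_BASE_Q48,) * 5 + (_BASE_Q910,) * 2
DEFAULT_HEAVY_ITEMS: tuple[tuple[float, ...], ...] = (_HEAVY_Q13,) * 3 + (_HEAVY_Q48,) * 5 + (_HEAVY_Q910,) * 2

#: How strongly the drinking propensity shifts each item towards the heavy
#: distribution. Items 1-3 (the AUDIT-C consumption items the binge-drinker
#: presets read) move the most; the harm items move less.
DEFAULT_ITEM_STRENGTH: tuple[float, ...] = (1.0,) * 3 + (0.4,) * 5 + (0.3,) * 2


def _check_pvec(name: str, vec: Sequence[float], length: int) -> np.ndarray:
    arr = np.asarray(vec, dtype=float)
    if arr.shape != (length,) or (arr < 0).any() or abs(arr.sum() - 1.0) > 1e-9:
        raise ValidationError(
            f"{name} must be {length} non-negative probabilities summing to 1, got {vec}"
        )
    return arr


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-shape and distributional knobs for :func:`generate_study`.

    Defaults emulate nine classrooms of 23-25 students (~214 total, half
    female), four friendship groups per classroom, within-group contact
    ratings concentrated on 4-5 and between-group on 1-2, a 25% chance that
    the two directions of a dyad are drawn independently rather than copied,
    and a drinking propensity that is a 60/40 group/individual mix.
    """

    n_classrooms: int = 9
    students_per_classroom: tuple[int, int] = (23, 25)  # inclusive range
    female_proportion: float = 0.5
    n_groups_per_classroom: int = 4
    within_group_rating_distribution: tuple[float, ...] = (0.03, 0.07, 0.20, 0.35, 0.35)
    between_group_rating_distribution: tuple[float, ...] = (0.60, 0.25, 0.10, 0.04, 0.01)
    rating_reciprocity_noise: float = 0.25
    drinking_homophily: float = 0.6
    base_audit_item_distributions: tuple[tuple[float, ...], ...] = DEFAULT_BASE_ITEMS
    heavy_audit_item_distributions: tuple[tuple[float, ...], ...] = DEFAULT_HEAVY_ITEMS
    audit_item_strength: tuple[float, ...] = DEFAULT_ITEM_STRENGTH
    seed: int = 0

    def validate(self) -> None:
        if self.n_classrooms < 1 or self.n_groups_per_classroom < 1:
            raise ValidationError("need at least one classroom and one group")
        lo, hi = self.students_per_classroom
        if not (2 <= lo <= hi):
            raise ValidationError("students_per_classroom must be a range with 2 <= lo <= hi")
        for p, name in (
            (self.female_proportion, "female_proportion"),
            (self.rating_reciprocity_noise, "rating_reciprocity_noise"),
            (self.drinking_homophily, "drinking_homophily"),
        ):
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {p}")
        _check_pvec("within_group_rating_distribution", self.within_group_rating_distribution, 5)
        _check_pvec("between_group_rating_distribution", self.between_group_rating_distribution, 5)
        if len(self.base_audit_item_distributions) != 10 or len(
            self.heavy_audit_item_distributions
        ) != 10 or len(self.audit_item_strength) != 10:
            raise ValidationError("AUDIT item distributions/strengths must cover 10 items")
        for i, (base, heavy) in enumerate(
            zip(self.base_audit_item_distributions, self.heavy_audit_item_distributions),
            start=1,
        ):
            length = 5 if i <= 8 else 3
            _check_pvec(f"base item {i} distribution", base, length)
            _check_pvec(f"heavy item {i} distribution", heavy, length)

    def with_seed(self, seed: int) -> "GeneratorConfig":
        return replace(self, seed=seed)


def _draw_audit_items(rng: np.random.Generator, config: GeneratorConfig, propensity: float):
    items = []
    for i in range(10):
        base = np.asarray(config.base_audit_item_distributions[i])
        heavy = np.asarray(config.heavy_audit_item_distributions[i])
        mix = config.audit_item_strength[i] * propensity
        p = (1.0 - mix) * base + mix * heavy
        values = (0, 1, 2, 3, 4) if i < 8 else (0, 2, 4)
        items.append(int(rng.choice(values, p=p / p.sum())))
    return tuple(items)


def generate_study(config: GeneratorConfig | None = None) -> ResponseSet:
    """Generate one synthetic roster study from a validated config.

    Per classroom: students get a gender and a planted friendship group;
    every ordered within-classroom dyad receives exactly one rating, the two
    directions of a dyad agreeing unless reciprocity noise redraws the second
    independently; each group draws a drinking propensity which is mixed with
    an individual draw by ``drinking_homophily`` and then shifts the AUDIT
    item distributions. Same seed, same study — byte-identical on disk.
    """
    config = config or GeneratorConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    individuals: list[Individual] = []
    ratings: list[DyadRating] = []
    lo, hi = config.students_per_classroom
    within = np.asarray(config.within_group_rating_distribution)
    between = np.asarray(config.between_group_rating_distribution)

    for c in range(config.n_classrooms):
        classroom_id = f"C{c + 1:02d}"
        n = int(rng.integers(lo, hi + 1))
        ids = [f"{classroom_id}S{s + 1:02d}" for s in range(n)]
        genders = np.where(
            rng.random(n) < config.female_proportion, "female", "male"
        )
        groups = rng.integers(0, config.n_groups_per_classroom, size=n)
        group_propensity = rng.random(config.n_groups_per_classroom)

        for idx, sid in enumerate(ids):
            own = rng.random()
            h = config.drinking_homophily
            propensity = h * group_propensity[groups[idx]] + (1.0 - h) * own
            individuals.append(
                Individual(
                    id=sid,
                    classroom_id=classroom_id,
                    gender=str(genders[idx]),
                    audit_items=_draw_audit_items(rng, config, propensity),
                    extra_attributes={"group": int(groups[idx])},
                )
            )

        for i in range(n):
            for j in range(i + 1, n):
                dist = within if groups[i] == groups[j] else between
                w_ij = int(rng.choice(WEIGHTS, p=dist))
                if rng.random() < config.rating_reciprocity_noise:
                    w_ji = int(rng.choice(WEIGHTS, p=dist))
                else:
                    w_ji = w_ij
                ratings.append(DyadRating(ids[i], ids[j], w_ij))
                ratings.append(DyadRating(ids[j], ids[i], w_ji))

    return ResponseSet(
        individuals,
        ratings,
        metadata={"study": "synthetic", "seed": str(config.seed)},
    )
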