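from __future__ import annotations

import numpy as np
import pytest

from rosterlens import (
    DyadRating,
    GeneratorConfig,
    Individual,
    ResponseSet,
    generate_study,
)


def make_individual(id="A", classroom="C1", gender="male", audit=None, **extras):
    return Individual(
        id=id,
        classroom_id=classroom,
        gender=gender,
        audit_items=audit,
        extra_attributes=extras,
    )


@pytest.fixture
def small_study() -> ResponseSet:
    """Five students in one classroom with hand-chosen ratings and AUDIT items.

    Strong-friendship (reciprocal, both >= 4) ties by construction: {A,B} and
    {C,D}; E is an isolate under that rule. AUDIT-C scores: A=9, B=5, C=2,
    D=0, E=12.
    """
    inds = [
        make_individual("A", gender="male", audit=(4, 3, 2, 0, 0, 0, 0, 0, 0, 0)),
        make_individual("B", gender="female", audit=(2, 2, 1, 0, 0, 0, 0, 0, 2, 0)),
        make_individual("C", gender="male", audit=(1, 1, 0, 0, 0, 0, 0, 0, 0, 0)),
        make_individual("D", gender="female", audit=(0, 0, 0, 0, 0, 0, 0, 0, 0, 0)),
        make_individual("E", gender="male", audit=(4, 4, 4, 0, 0, 0, 0, 0, 0, 0)),
    ]
    ratings = [
        DyadRating("A", "B", 5), DyadRating("B", "A", 4),
        DyadRating("C", "D", 4), DyadRating("D", "C", 4),
        DyadRating("A", "C", 3), DyadRating("C", "A", 3),
        DyadRating("B", "C", 2), DyadRating("C", "B", 1),
        DyadRating("E", "A", 5), DyadRating("A", "E", 1),
    ]
    return ResponseSet(inds, ratings, metadata={"study": "unit-fixture"})


@pytest.fixture
def synth_study() -> ResponseSet:
    """A small seeded synthetic study (3 classrooms) for integration tests."""
    return generate_study(
        GeneratorConfig(seed=7, n_classrooms=3, students_per_classroom=(12, 14))
    )


def random_raw_ratings(rng: np.random.Generator, n: int):
    """Random partial roster: each ordered pair rated with prob 0.7, weight 1-5."""
    ids = [f"N{i:02d}" for i in range(n)]
    weights: dict[tuple[str, str], int] = {}
    for a in ids:
        for b in ids:
            if a != b and rng.random() < 0.7:
                weights[(a, b)] = int(rng.integers(1, 6))
    return ids, weights


def random_tie_rule(rng: np.random.Generator):
    """A random valid TieRule drawn over the whole rule space."""
    from rosterlens import TieRule

    kwargs = {
        "name": f"r{rng.integers(10**6)}",
        "require_reciprocity": bool(rng.random() < 0.5),
    }
    while True:
        if rng.random() < 0.6:
            kwargs["min_each_weight"] = int(rng.integers(1, 6))
        if rng.random() < 0.4:
            kwargs["min_sum_weight"] = int(rng.integers(2, 11))
        if rng.random() < 0.4:
            kwargs["min_mean_weight"] = float(rng.integers(2, 11)) / 2
        if any(k in kwargs for k in ("min_each_weight", "min_sum_weight", "min_mean_weight")):
            return TieRule(**kwargs)
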