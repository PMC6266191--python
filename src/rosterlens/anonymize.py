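"""Pseudonymization of participant identifiers.

Pseudonyms are derived by keyed hashing (HMAC-SHA256) of the original id
under a study secret, so re-runs with the same secret map every participant
to the same pseudonym while the pseudonyms themselves carry no information
about the originals. Network structure and all metrics are invariant under
the renaming.
"""

from __future__ import annotations

import hashlib
import hmac

from .errors import ValidationError
from .questionnaire import DyadRating, Individual, ResponseSet


def _pseudonym(secret: str, original: str, length: int) -> str:
    digest = hmac.new(secret.encode(), original.encode(), hashlib.sha256).hexdigest()
    return "P" + digest[:length].upper()


def pseudonym_map(ids: list[str], secret: str) -> dict[str, str]:
    """Injective original-id -> pseudonym mapping, stable per secret.

    The digest prefix is lengthened until all pseudonyms are distinct (a
    collision at 10 hex characters is astronomically unlikely, but the
    bijection is an invariant, not a probability).
    """
    for length in range(10, 65):
        mapping = {orig: _pseudonym(secret, orig, length) for orig in ids}
        if len(set(mapping.values())) == len(mapping):
            return mapping
    raise ValidationError("could not derive collision-free pseudonyms")  # pragma: no cover


def anonymize(responses: ResponseSet, secret: str) -> tuple[ResponseSet, dict[str, str]]:
    """Replace every id consistently across individuals and ratings.

    Returns the pseudonymized study and the original->pseudonym map (to be
    stored separately from the released data).
    """
    mapping = pseudonym_map(sorted(responses.individuals), secret)
    individuals = [
        Individual(
            id=mapping[ind.id],
            classroom_id=ind.classroom_id,
            gender=ind.gender,
            audit_items=ind.audit_items,
            extra_attributes=dict(ind.extra_attributes),
        )
        for ind in responses.individuals.values()
    ]
    ratings = [
        DyadRating(mapping[r.rater], mapping[r.ratee], r.weight)
        for r in responses.ratings.values()
    ]
    anon = ResponseSet(
        individuals,
        ratings,
        metadata={**responses.metadata, "anonymized": "true"},
        allow_cross_classroom=responses.allow_cross_classroom,
    )
    return anon, mapping
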