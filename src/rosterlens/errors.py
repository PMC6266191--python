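"""Exception hierarchy.

All user-facing failures derive from :class:`RosterlensError` so the CLI can
map them to a single non-zero exit code while library users can catch
narrower classes.
"""

from __future__ import annotations


class RosterlensError(Exception):
    """Base class for all rosterlens errors."""


class ValidationError(RosterlensError):
    """Input data violates an invariant (bad weight, self-rating, ...).

    ``row_errors`` collects per-row diagnostics as ``(row_number, message)``
    pairs when the error originates from a tabular file.
    """

    def __init__(self, message: str, row_errors: list[tuple[int, str]] | None = None):
        self.row_errors = row_errors or []
        if self.row_errors:
            detail = "; ".join(f"row {r}: {m}" for r, m in self.row_errors)
            message = f"{message} ({detail})"
        super().__init__(message)


class SchemaError(RosterlensError):
    """A file or config fragment does not match its documented schema."""


class RuleError(RosterlensError):
    """A tie or characteristic rule is malformed."""


class EvaluationError(RosterlensError):
    """A rule references a score source that cannot be resolved."""
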