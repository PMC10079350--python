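"""Typed exceptions raised across the package.

Every parser and numerical routine raises one of these rather than silently
truncating or returning sentinel values.
"""


class IsofuncError(Exception):
    """Base class for all package errors."""


class ParseError(IsofuncError, ValueError):
    """A file did not conform to its declared format."""


class DuplicateRecordError(ParseError):
    """Two records claim the same accession."""


class DegenerateDataError(IsofuncError, ValueError):
    """Input is structurally valid but too degenerate to operate on
    (empty annotation map, constant score vector, corpus with no
    eligible isoform pairs, ...)."""


class RankDeficiencyError(DegenerateDataError):
    """Least-squares design has fewer than three distinct shared-term
    counts; callers should fall back to the previous coefficient
    estimate (or resample the initialization subset)."""


class EnumerationGuardError(IsofuncError, ValueError):
    """Brute-force enumeration would exceed the configured bit budget."""
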