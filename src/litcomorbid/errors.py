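"""Exception hierarchy shared across the package."""


class LitComorbidError(Exception):
    """Base class for all package errors."""


class ParseError(LitComorbidError):
    """An input file violates its declared dialect or schema."""


class MappingError(LitComorbidError):
    """A disease mapping entry is malformed or empty."""


class PatternError(LitComorbidError):
    """A text pattern fails to compile or is rejected by the safety guard."""


class CohortError(LitComorbidError):
    """Cohort selection preconditions are violated (e.g. empty window)."""


class AdjudicationError(LitComorbidError):
    """A reviewer vote refers to a (patient, disease) pair with no match."""


class UndefinedStatisticError(LitComorbidError):
    """A statistic is undefined for the given input (signaled, never silent)."""
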