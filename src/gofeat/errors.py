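"""Exception hierarchy shared across the package."""


class GofeatError(Exception):
    """Base class for all package-specific errors."""


class ParseError(GofeatError):
    """A document could not be parsed (malformed stanza, dangling reference)."""


class StructuralError(GofeatError):
    """An ontology violates a structural invariant (e.g. cyclic is_a graph)."""


class LookupError_(GofeatError):
    """An identifier is unknown to the object being queried."""


class ValidationError(GofeatError):
    """An input value fails a precondition (bad residue, out-of-range length)."""


class UndefinedICError(GofeatError):
    """Information content is undefined because the parent count is zero."""


class CandidateRejected(GofeatError):
    """A GO term does not qualify for classifier training (too few instances,
    no feasible fold count, or an irrecoverably degenerate fold)."""


class NotReported(GofeatError):
    """A statistic falls below its minimum coverage and is not reported."""
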