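"""Exception hierarchy for funfor."""


class FunForError(Exception):
    """Base class for all funfor errors."""


class InvalidGridError(FunForError):
    """Grid points are not strictly increasing, or too few of them."""


class InvalidInputError(FunForError):
    """Inputs violate a documented precondition (shape, symmetry, values)."""


class InvalidNodeError(FunForError):
    """A tree-node operation was invoked on an empty node."""


class InsufficientDataError(FunForError):
    """Too few observations for the requested estimate (e.g. covariance with n < 2)."""


class NumericalError(FunForError):
    """A linear system or decomposition failed; carries a diagnostic message."""


class NoOobCoverageError(FunForError):
    """A training row is in-bag for every tree, so no out-of-bag prediction exists."""


class ParseError(FunForError):
    """A delimited-text input could not be parsed; names the offending row/column."""


class ProvenanceError(FunForError):
    """Input checksums do not match the model's recorded provenance."""
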