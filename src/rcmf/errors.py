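"""Exception hierarchy for rcmf.

All rcmf-specific failures derive from :class:`RcmfError` so callers can
catch the whole family; each concrete class also derives from the closest
builtin (``ValueError``/``KeyError``) for idiomatic handling.
"""


class RcmfError(Exception):
    """Base class for all rcmf errors."""


class IdentifierError(RcmfError, KeyError):
    """An miRNA/disease/DAG-term identifier is unknown."""

    def __str__(self) -> str:  # KeyError quotes its message; keep it plain
        return Exception.__str__(self)


class DomainError(RcmfError, ValueError):
    """An argument is outside the operation's mathematical domain."""


class AlignmentError(RcmfError, ValueError):
    """Labels of two matrices that must agree do not."""


class ParseError(RcmfError, ValueError):
    """A file does not satisfy its format contract."""


class DegenerateInputError(RcmfError, ValueError):
    """Input is structurally valid but numerically degenerate (e.g. all-zero)."""


class NumericError(RcmfError, ValueError):
    """Non-finite values where finite ones are required."""


class DivergenceError(RcmfError, RuntimeError):
    """The alternating solver's objective increased sharply; fit aborted."""


class UndefinedAUCError(RcmfError, ValueError):
    """AUC requested with only one class present."""
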