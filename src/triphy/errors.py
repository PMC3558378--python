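"""Exception hierarchy shared by all triphy modules."""


class TriphyError(Exception):
    """Base class for all package errors."""


class FormatError(TriphyError):
    """Malformed input in a matrix dialect, or an unwritable matrix."""


class MissingValueError(FormatError):
    """A matrix cell holds the missing marker ('*' or '?'); full rows are required."""


class StateArityError(FormatError):
    """A character column realizes four or more distinct states."""


class ObstructionError(TriphyError):
    """A chordless 4-cycle on two colors was met where none should exist."""


class NotChordalError(TriphyError):
    """Maximum cardinality search exposed a missing chord."""


class ParameterError(TriphyError):
    """A generator was called with unsatisfiable parameters."""


class SizeLimitError(TriphyError):
    """A brute-force oracle was asked to exceed its hard size guard."""


class InternalInconsistencyError(TriphyError):
    """A structural guarantee was violated; signals an implementation bug."""
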