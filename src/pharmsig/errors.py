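"""Exception hierarchy.

All validation failures raise a subclass of :class:`PharmsigError` so callers
(and the CLI) can distinguish bad input from genuine bugs.
"""


class PharmsigError(Exception):
    """Base class for all package-specific errors."""


class FormatError(PharmsigError):
    """A file does not conform to the expected dialect (missing column,
    non-numeric cell, unknown label...)."""


class ValidationError(PharmsigError):
    """An in-memory structure violates a type invariant."""


class SeparationError(PharmsigError):
    """Logistic fit abandoned because of complete or quasi-complete
    separation; estimates would be meaningless."""


class ConvergenceError(PharmsigError):
    """Iterative fit failed to converge within its iteration budget."""
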