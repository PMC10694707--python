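"""Exception hierarchy.

Everything raised on purpose by this package derives from
:class:`CPDomainsError`, so callers (and the CLI) can catch one type.
"""


class CPDomainsError(Exception):
    """Base class for all errors raised by cpdomains."""


class InvalidInputError(CPDomainsError, ValueError):
    """An argument violates a documented precondition."""


class InsufficientDataError(CPDomainsError, ValueError):
    """Too few observations for the requested computation."""


class InsufficientDurationError(InsufficientDataError):
    """A breath series is too short for the requested averaging window."""


class SingularFitError(CPDomainsError, ValueError):
    """Degenerate design (e.g. duplicated exhaustion times) makes a fit singular."""


class FitFailureError(CPDomainsError, RuntimeError):
    """A nonlinear fit did not converge; the message carries diagnostics."""


class ProtocolFailureError(CPDomainsError, RuntimeError):
    """A simulated or stepped protocol left its configured operating range."""


class BoundaryNotBracketedError(CPDomainsError, ValueError):
    """The tested work rates do not bracket the severe/extreme boundary."""


class SchemaError(CPDomainsError, ValueError):
    """A delimited input table is missing required columns."""


class ParseError(CPDomainsError, ValueError):
    """A delimited input table has malformed cells; message lists line numbers."""


class IntegrityError(CPDomainsError, ValueError):
    """Referential integrity violated between study tables."""
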