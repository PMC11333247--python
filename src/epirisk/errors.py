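"""Exception hierarchy shared across the package."""


class EpiRiskError(Exception):
    """Base class for all errors raised by epirisk."""


class InputDomainError(EpiRiskError, ValueError):
    """A value lies outside its documented domain (e.g. a level off the grid)."""


class ValidationError(EpiRiskError, ValueError):
    """A parsed input failed structural validation; the message names the row/rule."""


class DegenerateRowError(EpiRiskError, ValueError):
    """Raised by the ``error`` degenerate-row policy when a raw transition row is all-zero."""
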