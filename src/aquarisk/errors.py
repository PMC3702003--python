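"""Exception hierarchy shared across the package.

Validation errors signal ill-formed inputs (bad tables, impossible values);
domain errors signal well-formed inputs outside the domain of an operation
(an age past the last interval, a compound absent from a campaign).
"""


class AquariskError(Exception):
    """Base class for all package errors."""


class ValidationError(AquariskError):
    """Input violates a structural or value constraint."""


class ParseError(ValidationError):
    """A tabular input file could not be parsed."""


class DomainError(AquariskError):
    """A request lies outside the domain covered by the data."""


class NotAssessableError(AquariskError):
    """A compound carries no toxicity basis and cannot be risk-assessed."""
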