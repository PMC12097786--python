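"""Exception hierarchy.

``ConfigurationError`` — invalid simulation or analysis configuration.
``ValidationError``   — malformed or inconsistent data (bad trial tables,
                        unsorted spike trains, referential integrity).
``DomainError``       — mathematically invalid input to an operation
                        (negative rate envelope, nonpositive amplitude).
"""


class SubneuroError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SubneuroError, ValueError):
    pass


class ValidationError(SubneuroError, ValueError):
    pass


class DomainError(SubneuroError, ValueError):
    pass
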