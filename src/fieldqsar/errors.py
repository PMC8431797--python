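"""Exception hierarchy shared across the package."""


class QSARError(Exception):
    """Base class for all package-specific errors."""


class FormatError(QSARError):
    """A file or table does not conform to the expected layout."""


class ValidationError(QSARError):
    """Input data violates a documented invariant."""


class DomainError(QSARError, ValueError):
    """A numeric argument lies outside the mathematical domain of an operation."""


class ConfigError(QSARError):
    """A configuration references unknown properties or inconsistent settings."""


class DegenerateInputError(QSARError):
    """Input is structurally degenerate (collinear points, empty blocks, ...)."""
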