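"""Exception hierarchy shared across the package.

``ValidationError`` maps to CLI exit code 2, ``ComputationError`` to 3.
"""


class CarotlabError(Exception):
    """Base class for all package errors."""


class ValidationError(CarotlabError, ValueError):
    """Invalid user input: bad factor spec, malformed table, out-of-range value."""


class DomainError(ValidationError):
    """A numeric argument outside the mathematical domain of an operation."""


class OutOfRangeError(ValidationError):
    """A value outside the interval an operation is defined on (no extrapolation)."""


class DesignError(ValidationError):
    """A design table violating Box-Behnken structural invariants."""


class ComputationError(CarotlabError, RuntimeError):
    """A computation that cannot proceed: rank deficiency, degenerate surface."""


class RankDeficiencyError(ComputationError):
    """Model matrix is singular; carries the offending columns."""

    def __init__(self, message: str, columns=()):
        super().__init__(message)
        self.columns = tuple(columns)


class InsufficientDataError(ComputationError):
    """Too few usable observations after exclusions."""


class ChemistryError(ValidationError):
    """A molecular composition that cannot form the requested product."""
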