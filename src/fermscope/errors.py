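"""Exception hierarchy.

All package-raised errors derive from :class:`FermscopeError` so the CLI can
map any stage failure onto a single exit code.
"""


class FermscopeError(Exception):
    """Base class for all fermscope errors."""


class InvalidScenarioError(FermscopeError, ValueError):
    """A simulation scenario violates its invariants (e.g. dt <= 0)."""


class IntegrationFailureError(FermscopeError, ArithmeticError):
    """Numerical state became non-finite during ODE integration."""


class DesignError(FermscopeError, ValueError):
    """An experimental design is inconsistent with the available samples."""


class InsufficientDataError(FermscopeError, ValueError):
    """Too few observations for the requested statistic."""


class DomainError(FermscopeError, ValueError):
    """An input value lies outside the mathematical domain of an operation."""


class MissingDataError(FermscopeError, KeyError):
    """A required column or channel is absent."""
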