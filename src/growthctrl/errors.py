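"""Exception hierarchy shared across the package."""


class GrowthCtrlError(Exception):
    """Base class for all package errors."""


class IdentifierError(GrowthCtrlError, KeyError):
    """An unknown amino-acid / gene / condition identifier was supplied."""


class DomainError(GrowthCtrlError, ValueError):
    """An input value lies outside the mathematically valid domain."""


class FitError(GrowthCtrlError, RuntimeError):
    """A parameter-fitting problem was infeasible or singular.

    Carries optional per-entity diagnostics in ``diagnostics``.
    """

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class IntegrationError(GrowthCtrlError, RuntimeError):
    """An ODE integration failed; ``snapshot`` holds the last known state."""

    def __init__(self, message, snapshot=None):
        super().__init__(message)
        self.snapshot = snapshot
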