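"""Exception types shared across the package."""


class MitoswitchError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(MitoswitchError, ValueError):
    """A parameter or input violates a model invariant."""


class InvalidModelError(ValidationError):
    """The requested reaction network cannot be constructed."""


class IntegrationError(MitoswitchError, RuntimeError):
    """The ODE solver failed; carries the last valid state reached."""

    def __init__(self, message, last_time=None, last_state=None):
        super().__init__(message)
        self.last_time = last_time
        self.last_state = last_state


class AmbiguousCrossingError(MitoswitchError, ValueError):
    """A threshold was crossed more than once, so the crossing time is ill-defined."""


class AccuracyError(MitoswitchError, RuntimeError):
    """A numerical routine could not reach the requested tolerance."""

    def __init__(self, message, achieved=None):
        super().__init__(message)
        self.achieved = achieved
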