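"""Exception hierarchy for the rept package."""


class ReptError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(ReptError, ValueError):
    """Psychometric-function parameters violate their domain constraints."""


class UnattainableAccuracyError(ParameterError):
    """Requested accuracy lies outside the open interval (gamma, 1 - lapse)."""


class ConfigError(ReptError, ValueError):
    """A staircase or design configuration is malformed."""


class StateError(ReptError, RuntimeError):
    """An operation was applied to a staircase state that does not admit it."""


class DesignError(ReptError, ValueError):
    """A constant-stimuli design cannot be constructed as requested."""


class FitError(ReptError, RuntimeError):
    """A maximum-likelihood psychometric fit is non-identifiable or unstable."""


class SafetyIntervalError(ReptError, RuntimeError):
    """A pulse was requested before the minimum inter-pulse interval elapsed."""


class ReplayDivergenceError(ReptError, RuntimeError):
    """Replaying a session log did not reproduce the logged trial sequence."""


class AbortedSessionError(ReptError, RuntimeError):
    """A responder failed mid-run; carries the partial trial history."""

    def __init__(self, message: str, history=()):
        super().__init__(message)
        self.history = tuple(history)
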