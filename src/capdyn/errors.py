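"""Exception types shared across the pipeline."""


class CapdynError(Exception):
    """Base class for package errors."""


class ConfigurationError(CapdynError, ValueError):
    """A simulation or analysis configuration is internally inconsistent."""


class InputError(CapdynError, ValueError):
    """User-supplied data violates a documented precondition."""


class DegenerateInputError(InputError):
    """Input is formally valid but admits no meaningful solution
    (e.g. more clusters requested than distinct frames)."""


class ConvergenceError(CapdynError, RuntimeError):
    """An iterative fit failed to converge; carries the last iterate."""

    def __init__(self, message, last_result=None):
        super().__init__(message)
        self.last_result = last_result
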