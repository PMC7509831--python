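"""Exception hierarchy shared across the pipeline stages."""


class NPAmyloidError(Exception):
    """Base class for all package errors."""


class DataError(NPAmyloidError):
    """Invalid or contract-violating input data (CLI exit code 3)."""


class PackingError(NPAmyloidError):
    """System initialization failed: density too high.

    Carries the number density that was requested so callers can report it.
    """

    def __init__(self, message: str, achieved_density: float | None = None):
        super().__init__(message)
        self.achieved_density = achieved_density


class NoTransitionError(DataError):
    """A fluorescence curve has no usable sigmoidal transition."""


class ConvergenceError(NPAmyloidError):
    """A nonlinear fit failed to converge (CLI exit code 4)."""
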