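"""Exception hierarchy shared by all stages of the pipeline."""


class TetraFESError(Exception):
    """Base class for all package errors."""


class InputError(TetraFESError, ValueError):
    """A structurally invalid input (bad labels, shapes, or parameter values)."""


class ParseError(TetraFESError, ValueError):
    """A file could not be parsed; carries the offending line where known."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)
        self.line = line


class DomainError(TetraFESError, ValueError):
    """A point lies outside the domain of an analytic surface."""


class InstabilityError(TetraFESError, RuntimeError):
    """A sampler diverged; the message names the timestep that caused it."""


class DivergenceError(TetraFESError, RuntimeError):
    """An optimisation produced non-finite losses; names the learning rate."""


class SamplingFailure(TetraFESError, RuntimeError):
    """A constrained sampler failed to retain any sample (names the image)."""
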