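"""Exception hierarchy shared by all fastspike modules."""


class FastspikeError(Exception):
    """Base class for all errors raised by fastspike."""


class FormatError(FastspikeError):
    """A sweep or table file violates the expected on-disk format."""


class ValidationError(FastspikeError):
    """An in-memory object or argument violates its invariants."""


class PreconditionError(ValidationError):
    """An operation was called on data that does not satisfy its preconditions."""


class InsufficientDataError(FastspikeError):
    """Too few usable sweeps/steps/values to compute the requested quantity."""


class FitError(FastspikeError):
    """A model fit failed to converge or was attempted on degenerate data."""


class MeasurementError(FastspikeError):
    """A per-event measurement (threshold, half-width, trough) is undefined on this trace."""


class SimulationError(FastspikeError):
    """Numerical integration of the model neuron became unstable."""
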