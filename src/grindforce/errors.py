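"""Exception hierarchy for grindforce."""


class GrindforceError(Exception):
    """Base class for all package-specific errors."""


class TraceFormatError(GrindforceError):
    """A trace file or in-memory trace violates the expected format."""


class InfeasibleConditionError(GrindforceError):
    """A grinding condition cannot be realized by the generator.

    Raised when a planted spike cannot simultaneously lie in its signed
    peak range and satisfy the 5 N detection rule, or when repeated
    resampling never yields a trace the reference detector validates.
    """

    def __init__(self, axis: str, message: str):
        self.axis = axis
        super().__init__(f"axis {axis}: {message}")


class NoActiveSegmentError(GrindforceError):
    """No sample of the resultant force exceeds the onset threshold."""


class DegenerateTraceError(GrindforceError):
    """An operation has no usable samples left (e.g. all samples are spikes)."""
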