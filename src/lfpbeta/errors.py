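"""Exception taxonomy shared across the pipeline."""


class LfpBetaError(Exception):
    """Base class for all pipeline errors."""


class InvalidParameterError(LfpBetaError, ValueError):
    """A parameter violates its documented constraint."""


class InsufficientDataError(LfpBetaError, ValueError):
    """The input is too short or too small for the requested operation."""


class FormatError(LfpBetaError, ValueError):
    """A file does not conform to the expected on-disk format."""


class InfeasibleScheduleError(LfpBetaError, ValueError):
    """Requested event schedule cannot fit in the recording."""


class UndefinedSNRError(LfpBetaError, ValueError):
    """SNR is undefined (empty event or baseline segment, or zero baseline)."""
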