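"""Exception hierarchy for the spiraltremor pipeline.

All errors derive from :class:`SpiralTremorError` (itself a ``ValueError``)
so callers can catch either the package root or plain ``ValueError``.
"""


class SpiralTremorError(ValueError):
    """Base class for all spiraltremor errors."""


class InvalidParameterError(SpiralTremorError):
    """A parameter is outside its valid domain (non-positive duration, ...)."""


class SchemaError(SpiralTremorError):
    """A CSV file is missing required columns or has no data rows."""


class DataError(SpiralTremorError):
    """Data values violate an invariant (non-monotone time, negative pressure)."""


class NoPenDownError(SpiralTremorError):
    """The pen trace contains no sample with pressure > 0."""


class AlignmentError(SpiralTremorError):
    """The accelerometer trace does not overlap the task window."""


class TooShortError(SpiralTremorError):
    """The signal is too short for filtering or spectral estimation."""


class AliasingError(SpiralTremorError):
    """Sampling rate is insufficient for the requested tremor frequency."""


class InvalidBandError(SpiralTremorError):
    """A frequency band lies outside [0, fs/2] or is ill-ordered."""


class UndefinedRatioError(SpiralTremorError):
    """The low-band power is at the machine-precision floor; ratio undefined."""


class DegenerateInputError(SpiralTremorError):
    """Input is degenerate for the requested statistic (e.g. constant vector)."""


class SampleSizeError(SpiralTremorError):
    """Too few observations for the requested statistic."""


class CollinearityError(SpiralTremorError):
    """Regression design matrix is rank deficient (constant or duplicated predictor)."""


class ConfigError(SpiralTremorError):
    """Pipeline configuration failed validation; message names the offending key."""
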