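"""Exception types shared across the pipeline."""


class ArtSrnaError(Exception):
    """Base class for all package errors."""


class ParseError(ArtSrnaError):
    """A sequence file or header could not be parsed."""


class ConfigError(ArtSrnaError):
    """A run or simulation configuration failed validation."""


class UndefinedStatisticError(ArtSrnaError):
    """A ratio statistic was requested with a zero denominator.

    The pipeline distinguishes "no qualifying reads were observed" from a
    value of zero; callers that want NA semantics catch this exception.
    """
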