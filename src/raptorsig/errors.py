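"""Exception hierarchy shared across the pipeline."""


class RaptorsigError(Exception):
    """Base class for all package-specific errors."""


class DataIntegrityError(RaptorsigError):
    """Input data contradicts itself (e.g. a variant beyond its scaffold end)."""


class InvalidSequenceError(RaptorsigError):
    """A sequence contains characters the operation cannot interpret."""


class UndefinedStatisticError(RaptorsigError):
    """The requested statistic has no defined value for this input
    (zero-length window, all-gap column, zero callable bases, ...)."""


class SaturationError(RaptorsigError):
    """A substitution proportion is at or beyond 3/4, where the
    Jukes-Cantor correction is undefined."""
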