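"""Exception hierarchy.

``ConfigError`` maps to CLI exit code 2, ``DataError`` (and subclasses) to 3.
"""


class MRChainError(Exception):
    """Base class for all package errors."""


class ConfigError(MRChainError):
    """Invalid configuration: bad parameter values, missing columns, bad paths."""


class DataError(MRChainError):
    """Input data cannot support the requested computation."""


class EmptyOverlapError(DataError):
    """Exposure and outcome share no usable variants."""


class NoInstrumentsError(DataError):
    """No instruments survive quality control; carries the QC tally."""

    def __init__(self, message, tally=None):
        super().__init__(message)
        self.tally = dict(tally or {})


class InsufficientInstrumentsError(DataError):
    """Fewer variants than an estimator's minimum (e.g. Egger needs k >= 3)."""


class DegenerateInstrumentError(DataError):
    """An instrument has zero exposure effect, so its Wald ratio is undefined."""


class CollinearityError(DataError):
    """Multivariable exposure matrix is rank deficient."""


class UndefinedProportionError(DataError):
    """Total effect is zero, so the proportion mediated is undefined.

    The partial estimate (indirect effect and its SE) is attached as
    ``.estimate``.
    """

    def __init__(self, message, estimate=None):
        super().__init__(message)
        self.estimate = estimate


class PairingError(DataError):
    """Forward and reverse results do not refer to the same trait pair."""
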