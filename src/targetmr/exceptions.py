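"""Exception hierarchy for targetmr.

Every error raised by the package derives from :class:`TargetMRError`, so
callers orchestrating many targets can catch one base class, log, and move
on to the next target.
"""


class TargetMRError(Exception):
    """Base class for all targetmr errors."""


class ConfigurationError(TargetMRError):
    """A config file, column map, or parameter is malformed or missing."""


class EmptyInputError(TargetMRError):
    """An input file contained a header but no data rows."""


class NoOverlapError(TargetMRError):
    """Exposure and outcome summary statistics share no usable SNPs."""


class UnknownTargetError(TargetMRError, KeyError):
    """A requested gene symbol is not in the bundled instrument table."""


class MissingSNPError(TargetMRError, KeyError):
    """A SNP required for LD computation is absent from the reference."""


class DomainError(TargetMRError, ValueError):
    """A numeric argument is outside its mathematical domain."""


class UndefinedRatioError(DomainError):
    """Wald ratio requested with a zero exposure effect."""


class DegenerateWeightError(DomainError):
    """An inverse-variance weight is infinite (zero outcome SE)."""


class InsufficientInstrumentsError(TargetMRError):
    """Too few instruments for the requested estimator or diagnostic."""


class EmptyInstrumentSetError(TargetMRError):
    """Instrument filtering removed every SNP for a target."""
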