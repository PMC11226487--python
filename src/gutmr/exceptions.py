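"""Exception hierarchy for the gutmr pipeline."""


class GutMRError(Exception):
    """Base class for all gutmr errors."""


class ConfigurationError(GutMRError):
    """A column map, manifest, or config file is malformed or incomplete."""


class EmptyInputError(GutMRError):
    """An input table contained no valid rows."""


class DuplicateSNPError(GutMRError):
    """A summary-statistics collection contains the same snp_id twice."""


class InsufficientInstrumentsError(GutMRError):
    """Too few instruments remain for the requested estimator or diagnostic."""


class CollinearityError(GutMRError):
    """Exposure effects have zero variance; a regression with intercept is undefined."""


class UndefinedRatioError(GutMRError):
    """A Wald ratio was requested for an instrument with zero exposure effect."""
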