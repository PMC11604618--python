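"""Exception hierarchy for the tsmr package."""


class TsmrError(Exception):
    """Base class for all tsmr errors."""


class ConfigurationError(TsmrError):
    """A required column, LD pair, or configuration value is missing or invalid."""


class EmptyInputError(TsmrError):
    """An input table contained zero valid rows after validation."""


class EmptyOverlapError(TsmrError):
    """Exposure and outcome summary statistics share no SNPs."""


class EmptyInstrumentError(TsmrError):
    """Instrument selection emptied the candidate set.

    Parameters
    ----------
    stage : str
        Filter stage at which the set became empty
        (``p_threshold``, ``clump``, ``harmonization`` or ``f_filter``).
    """

    def __init__(self, stage: str, message: str | None = None):
        self.stage = stage
        super().__init__(message or f"no instruments survive stage '{stage}'")


class ArityError(TsmrError):
    """Too few instruments for the requested estimator or diagnostic."""


class DegenerateInstrumentError(TsmrError):
    """An instrument with zero exposure effect cannot form a Wald ratio."""


class CollinearityError(TsmrError):
    """MVMR design matrix is (numerically) rank deficient."""


class EligibilityError(TsmrError):
    """A mediation leg failed the unidirectional-causality precondition."""


class DegenerateCorrectionError(TsmrError):
    """MR-PRESSO flagged every instrument; no corrected estimate exists."""
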