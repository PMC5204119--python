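"""Exception hierarchy shared across the pipeline."""


class LncestroError(Exception):
    """Base class for all errors raised by this package."""


class InvalidConfigError(LncestroError):
    """A configuration object violates its invariants."""


class InvalidParameterError(LncestroError):
    """A single parameter is outside its admissible range."""


class CalibrationError(LncestroError):
    """The calibration set cannot constrain the signal-compression exponent."""


class InsufficientReplicationError(LncestroError):
    """Fewer than two replicates per condition for a statistical test."""


class MalformedGeneError(LncestroError):
    """A gene does not carry the expected number of probes."""


class NormalizationError(LncestroError):
    """The qPCR reference gene is absent from one or both conditions."""


class DegenerateInputError(LncestroError):
    """Input with zero variance or too few points for a correlation."""


class CoordinateError(LncestroError):
    """Feature coordinates fall outside the genome sequence."""


class CatalogueFormatError(LncestroError):
    """A gene catalogue contains malformed exon intervals."""


class EmptySummaryError(LncestroError):
    """A summary was requested over an empty gene set."""


class MissingInputError(LncestroError):
    """A pipeline stage input file does not exist."""


class StageError(LncestroError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage
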