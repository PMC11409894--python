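"""Exception types shared across the pipeline stages."""


class OrcadietError(Exception):
    """Base class for all package-specific errors."""


class InvalidDesignError(OrcadietError):
    """A simulation or mock-community design is structurally invalid."""


class InvalidCompositionError(OrcadietError):
    """A composition vector has negative entries or does not sum to 1."""


class EmptySampleError(OrcadietError):
    """A sample has zero total reads where reads are required."""


class UnknownSpeciesError(OrcadietError):
    """Observed counts contain a species absent from the mock design."""


class EmptyResultError(OrcadietError):
    """A filtering step removed every sample (or every species)."""


class UndefinedDistanceError(OrcadietError):
    """Two genotypes share no co-genotyped locus."""


class InsufficientDataError(OrcadietError):
    """A group has too few distinct time points for trend estimation."""
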