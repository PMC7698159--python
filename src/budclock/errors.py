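"""Exception hierarchy shared by all budclock modules."""


class BudclockError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(BudclockError):
    """An input file violates its declared tabular format."""


class EmptyDesignError(BudclockError):
    """A filtering step left the experimental design with no samples."""


class DegenerateSampleError(BudclockError):
    """A sample column sums to zero and cannot be normalized."""


class MissingGeneError(BudclockError):
    """A requested gene id is absent from a matrix or annotation."""


class CovariateCoverageError(BudclockError):
    """A sampling date is not covered by the environmental series."""


class UndefinedCorrelationError(BudclockError):
    """Correlation is undefined because one input vector is constant."""


class SamplingError(BudclockError):
    """A random draw was requested from a too-small eligible pool."""


class EmptyRankingError(BudclockError):
    """No gene survived the expression filter for the stability ranking."""


class EmptyHeatmapError(BudclockError):
    """Every family member fell below the detectability threshold."""


class UnsupportedLatitudeError(BudclockError):
    """Latitude outside the supported (non-polar) range."""


class UndefinedScoreError(BudclockError):
    """Stability score undefined (median of the expression vector is zero)."""


class ConfigError(BudclockError):
    """Invalid simulation or pipeline configuration."""
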