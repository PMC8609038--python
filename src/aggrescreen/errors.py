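"""Exception hierarchy shared across the pipeline stages."""


class AggrescreenError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(AggrescreenError):
    """A simulation or run configuration violates its invariants."""


class SchemaError(AggrescreenError):
    """An input table is missing required columns or carries bad labels."""


class UndefinedValueError(AggrescreenError):
    """A statistic is undefined for the given input (e.g. empty set, zero denominator)."""


class DegenerateDistributionError(AggrescreenError):
    """Standardization requested on a zero-variance sample."""


class IncompleteDoseSeriesError(AggrescreenError):
    """A compound is missing a z-score at one or more concentration tiers."""


class ParameterError(AggrescreenError):
    """A detection/segmentation parameter is out of its valid range."""


class PlacementError(AggrescreenError):
    """Synthetic objects could not be placed in the frame within the retry budget."""
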