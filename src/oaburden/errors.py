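"""Exception hierarchy for input validation and table lookups."""


class OABurdenError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(OABurdenError, ValueError):
    """A model or generator parameter is outside its admissible range."""


class DomainError(OABurdenError, ValueError):
    """A value passed to a model function is outside the function's domain."""


class TableLookupError(OABurdenError, KeyError):
    """A required (stratum, age band) entry is missing from an input table."""


class AlignmentError(OABurdenError, ValueError):
    """Two tables that must share a key set do not align."""


class CompletenessError(OABurdenError, ValueError):
    """A stratified computation is missing required strata."""


class DegenerateDistributionError(OABurdenError, ValueError):
    """A weighting distribution has zero total mass."""


class IntegrityError(OABurdenError, RuntimeError):
    """A packaged fixture file is missing or fails its checksum."""


class SchemaError(OABurdenError, ValueError):
    """A CSV file does not conform to its declared schema."""
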