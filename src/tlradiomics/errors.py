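"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: ConfigError -> 2, DataError -> 3.
"""


class TlradiomicsError(Exception):
    """Base class for package errors."""


class ParameterError(TlradiomicsError, ValueError):
    """An argument is outside its documented domain."""


class ConfigError(TlradiomicsError, ValueError):
    """A run configuration is inconsistent or unserialisable."""


class DataError(TlradiomicsError, ValueError):
    """Input data violate a precondition (e.g. a single-class label vector)."""


class ShapeError(TlradiomicsError, ValueError):
    """Array dimensions do not match the model or configuration."""


class SchemaError(TlradiomicsError, KeyError):
    """A required column or feature id is missing."""


class GeometryError(TlradiomicsError, ValueError):
    """A crop or region does not intersect the image."""


class LeakageError(TlradiomicsError, ValueError):
    """Train and validation cohorts share patients."""


class NumericError(TlradiomicsError, ArithmeticError):
    """Non-finite values where finite ones are required."""


class FingerprintError(TlradiomicsError, ValueError):
    """Domain embeddings come from different extractors."""


class EnumerationLimitError(TlradiomicsError, ValueError):
    """An exact test's enumeration space is too large."""
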