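"""Exception hierarchy.

Every error raised on a user-facing contract violation derives from
:class:`DrSimError`, so callers (and the CLI) can distinguish input
problems (exit code 1) from genuine bugs (exit code 2).
"""


class DrSimError(Exception):
    """Base class for all package errors."""


class FormatError(DrSimError):
    """A file does not conform to its declared format (GCT header, counts...)."""


class ParseError(DrSimError):
    """A cell or field could not be parsed; message carries coordinates."""


class ValidationError(DrSimError):
    """Data violates a structural invariant (duplicate ids, bad shapes...)."""


class SchemaError(DrSimError):
    """A table lacks a required column."""


class CoverageError(DrSimError):
    """Query/model gene overlap below the required fraction."""


class EmptySelectionError(DrSimError):
    """A filter removed every sample or every class."""


class SubsetLookupError(DrSimError):
    """No subset with the requested (cell line, time point) key."""


class ParameterError(DrSimError):
    """A hyperparameter outside its allowed range."""


class DegenerateInputError(DrSimError):
    """Too few samples/classes for the requested computation."""


class DegenerateSeparationError(DrSimError):
    """All discriminant eigenvalues are (numerically) zero."""


class ModeMisuseError(DrSimError):
    """A forward-mode operation applied to a reversed model, or vice versa."""


class UndefinedSimilarityError(DrSimError):
    """Cosine similarity requested for a zero vector."""


class UndefinedScoreError(DrSimError):
    """A connectivity score has no defined value (e.g., empty gene overlap)."""


class UndefinedMetricError(DrSimError):
    """An evaluation metric is undefined for the given inputs."""


class IntegrityError(DrSimError):
    """A persisted model directory is internally inconsistent."""


class CompatibilityError(DrSimError):
    """A persisted model has an unsupported format version."""


class ShapeError(DrSimError):
    """Vector/matrix dimensions do not match."""
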