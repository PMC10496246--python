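"""Exception hierarchy shared across the pipeline."""


class EleneError(Exception):
    """Base class for all package errors."""


class InvalidMetadataError(EleneError):
    """CT slice metadata violates its contract (e.g. non-positive window width)."""


class ContourError(EleneError):
    """Degenerate or self-intersecting contour polygon."""


class EmptyROIError(EleneError):
    """An operation received an empty mask / empty pixel selection."""


class ParameterError(EleneError):
    """An out-of-range parameter (radius, quantization levels, ...)."""


class Degenerate3DError(EleneError):
    """A 3D model cannot be built (e.g. single-slice node)."""


class EmptyPairsError(EleneError):
    """Patch too small for the requested co-occurrence displacement."""


class DegenerateMomentsError(EleneError):
    """Moments undefined (all-zero patch)."""


class ContractError(EleneError):
    """An internal contract was violated (e.g. unnormalized GLCM)."""


class FoldError(EleneError):
    """Too few samples per class for the requested cross-validation folds."""


class ConfigError(EleneError):
    """Invalid optimizer configuration."""


class InvalidChromosomeError(EleneError):
    """Chromosome violates its invariants (e.g. zero selected features)."""


class SchemaError(EleneError):
    """A feature table does not match the expected schema."""


class InputError(EleneError):
    """Malformed user input (length mismatches and similar)."""


class UndefinedAUCError(EleneError):
    """AUC requested with a single-class truth vector."""
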