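"""Typed errors raised by the pipeline.

Every malformed input raises one of these; nothing is silently dropped.
"""


class NGRScreenError(Exception):
    """Base class for all package errors."""


class SchemaError(NGRScreenError):
    """A required column is missing or has the wrong dtype."""


class IntegrityError(NGRScreenError):
    """Duplicate (plate, well, timepoint) rows or similar structural damage."""


class ValidationError(NGRScreenError):
    """Input values violate a declared contract (e.g. off-grid dose)."""


class MeasurementError(ValidationError, ValueError):
    """A measured quantity is out of range (e.g. negative area)."""


class ConfigError(NGRScreenError):
    """A configuration object is internally inconsistent."""


class DegenerateWellError(NGRScreenError):
    """Baseline viability is non-positive; growth is undefined for the well."""


class MissingControlError(NGRScreenError):
    """A plate/timepoint has no wells for a required control role."""


class PlateQCError(NGRScreenError):
    """Control medians have the wrong sign; the plate fails quality control."""


class InsufficientDataError(NGRScreenError):
    """Too few points (or too few distinct doses) to attempt a fit."""


class InsufficientReplicationError(NGRScreenError):
    """A statistical comparison needs >= 2 replicates per cell."""


class UndefinedFoldChangeError(NGRScreenError):
    """Fold change is undefined for non-positive inputs."""
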