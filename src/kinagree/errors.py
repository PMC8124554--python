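"""Exception taxonomy used across the pipeline."""


class KinagreeError(Exception):
    """Base class for all package errors."""


class FormatError(KinagreeError):
    """A file does not conform to the expected schema."""


class IntegrityError(KinagreeError):
    """Data violates an internal consistency requirement (e.g. time order)."""


class GeometryError(KinagreeError):
    """Degenerate geometry: coincident joints, zero-length vectors, ..."""


class LengthError(KinagreeError):
    """A series is too short for the requested operation."""


class ConfigError(KinagreeError):
    """An invalid or inconsistent configuration value."""


class SyncError(KinagreeError):
    """Time synchronization could not be established."""


class StatsError(KinagreeError):
    """Too few samples (or otherwise unusable data) for a statistic."""


class FitError(KinagreeError):
    """A regression fit could not be performed."""


class AlignmentError(KinagreeError):
    """Two series expected to be sample-aligned are not."""


class UsageError(KinagreeError):
    """An operation was applied to the wrong object (e.g. wrong angle name)."""


class StageOrderError(KinagreeError):
    """A pipeline stage was applied out of the mandated order."""
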