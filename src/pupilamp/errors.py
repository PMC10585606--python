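"""Exception hierarchy for the pupilamp pipeline.

Every stage raises a subclass of :class:`PupilampError`, so callers can
catch pipeline failures without masking programming errors.
"""


class PupilampError(Exception):
    """Base class for all pupilamp errors."""


class FormatError(PupilampError):
    """An input file does not have the expected columns or dtypes."""


class ConsistencyError(PupilampError):
    """Cross-references between samples and events do not line up."""


class SamplingError(PupilampError):
    """Timestamps are not uniform at the declared sampling rate."""


class EpochingError(PupilampError):
    """A trial window extends beyond the recorded run."""


class NormalizationError(PupilampError):
    """The series cannot be z-scored (zero variance or too short)."""


class ParameterError(PupilampError, ValueError):
    """A configuration or generator parameter is out of range."""


class TemplateError(PupilampError):
    """A response template cannot be built (empty or degenerate cell)."""


class RankError(PupilampError):
    """The per-trial design matrix is rank deficient."""


class ShapeError(PupilampError):
    """Array lengths of trial and template do not match."""


class BootstrapError(PupilampError):
    """The pseudo-trial split cannot be formed (too few trials)."""


class DesignError(PupilampError):
    """A factorial design is degenerate (confounded or all-tied)."""
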