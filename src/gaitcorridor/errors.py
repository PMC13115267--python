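"""Exception hierarchy for the gait pipeline.

Validation problems (bad config, malformed files) are kept distinct from
data problems (non-monotonic time, degenerate geometry) so the CLI can map
them onto exit codes 2 and 1 respectively.
"""


class GaitError(Exception):
    """Base class for all package errors."""


class FormatError(GaitError):
    """A file does not match the declared dialect (names the offending column)."""


class DataError(GaitError):
    """Structurally valid input carries impossible data (e.g. time not increasing)."""


class ConfigError(GaitError):
    """Invalid configuration, manifest or cohort specification."""


class ResolutionError(ConfigError):
    """A manifest references files that cannot be found."""


class GeometryError(GaitError):
    """Degenerate marker geometry (zero-length segment at the knee)."""


class SegmentationError(GaitError):
    """Gait-cycle event detection failed (too few extension peaks)."""


class UndefinedStatisticError(GaitError):
    """A statistic is undefined for the given input (e.g. zero variance)."""
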