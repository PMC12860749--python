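"""Exception hierarchy.

Every error raised by this package derives from :class:`MarrowQuantError`
so callers can catch the whole family at a pipeline boundary.
"""


class MarrowQuantError(Exception):
    """Base class for all marrowquant errors."""


class InvalidSpecError(MarrowQuantError):
    """A phantom/cohort specification violates its invariants."""


class InvalidInputError(MarrowQuantError):
    """An operation received an argument outside its domain."""


class AlignmentError(MarrowQuantError):
    """Two grids that must share geometry do not."""


class DegenerateMaskError(MarrowQuantError):
    """A mask is empty (or became empty) where a nonempty one is required."""


class DegenerateDataError(MarrowQuantError):
    """A statistic is undefined on the given data (constant vector, all-zero
    paired differences, both raters constant, ...)."""


class ConsistencyError(MarrowQuantError):
    """Mutually inconsistent inputs (e.g. lesion stats with a zero lesion count)."""


class FormatError(MarrowQuantError):
    """A file could not be read as the expected format."""


class ConfigError(MarrowQuantError):
    """A pipeline configuration failed validation."""
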