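"""Exception hierarchy for spatialtme."""


class SpatialTmeError(Exception):
    """Base class for all package-specific errors."""


class FormatError(SpatialTmeError):
    """A file is structurally malformed (missing column, missing feature)."""


class ValidationError(SpatialTmeError):
    """A file parses but contains invalid values (non-binary marker, negative time)."""


class GeometryError(SpatialTmeError):
    """An annotation geometry is unusable (self-intersecting, zero area)."""


class UsageError(SpatialTmeError):
    """An operation was called with arguments that violate its contract."""


class DegenerateSplitError(UsageError):
    """A median split was requested on values that cannot be dichotomized."""
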