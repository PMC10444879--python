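"""Exception hierarchy used across the pipeline."""


class TapscoreError(Exception):
    """Base class for all package errors."""


class SchemaError(TapscoreError):
    """A file or table does not follow the documented schema."""


class ValidationError(TapscoreError):
    """An in-memory object violates its invariants (e.g. malformed detection)."""


class DegenerateGeometryError(TapscoreError):
    """A geometric computation is undefined (zero-length vector, coincident points)."""


class EmptySegmentError(TapscoreError):
    """No visible segment exists in the angle signal."""


class InsufficientTapsError(TapscoreError):
    """Fewer detected taps than the analysis requires."""


class FeatureError(TapscoreError):
    """A feature cannot be computed from the given signal."""


class CapabilityError(TapscoreError):
    """An optional capability (e.g. the external pose estimator) is unavailable."""
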