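"""Exception hierarchy.

All loomkit errors derive from :class:`LoomkitError` so callers can catch the
package's failures with a single ``except``.  Errors that signal a violated
precondition subclass ``ValueError`` as well.
"""


class LoomkitError(Exception):
    """Base class for all loomkit errors."""


class ProtocolKindError(LoomkitError, ValueError):
    """A stimulus-protocol operation was called with the wrong protocol kind."""


class LabelError(LoomkitError, ValueError):
    """Unknown movement/motif label."""


class ScheduleError(LoomkitError, ValueError):
    """Scenario legs overlap or leave gaps."""


class GeometryError(LoomkitError, ValueError):
    """A simulated path leaves the arena ∪ refuge domain."""


class AlignmentError(LoomkitError, ValueError):
    """Egocentric alignment failed (degenerate body axis)."""


class SchemaError(LoomkitError, ValueError):
    """A pose/trajectory file does not match the documented schema."""


class DataQualityError(LoomkitError, ValueError):
    """Missing-data gaps too long to interpolate."""


class MappingError(LoomkitError, KeyError):
    """Phenotype IDs not covered by a label mapping."""


class EventError(LoomkitError, ValueError):
    """A required assay event (e.g. stimulus onset) is missing."""


class WindowError(LoomkitError, ValueError):
    """A requested ethogram window's defining events are absent."""


class DesignError(LoomkitError, ValueError):
    """Degenerate statistical design (fewer than two groups)."""


class AggregationError(LoomkitError, ValueError):
    """Aggregation over an empty phenotype/group."""


class ConfigError(LoomkitError, ValueError):
    """Invalid or incomplete pipeline configuration."""
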