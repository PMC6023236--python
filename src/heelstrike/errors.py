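"""Exception hierarchy for the heel-strike pipeline.

Every stage raises a subclass of :class:`HeelstrikeError` so that the
trial orchestrator can annotate failures with the stage name without
string-matching on messages.
"""


class HeelstrikeError(Exception):
    """Base class for all pipeline errors."""


class InputError(HeelstrikeError):
    """Malformed or inconsistent input data (lengths, monotonicity, units)."""


class DialectError(InputError):
    """A delimited file whose header matches no known dialect."""


class GapError(InputError):
    """A marker dropout longer than the interpolatable maximum."""


class GeometryError(HeelstrikeError):
    """Degenerate marker geometry (coincident LEDs, undefined frame axis)."""


class NoContactError(HeelstrikeError):
    """The vertical GRF never exceeds the contact rise threshold."""


class EventNotFoundError(HeelstrikeError):
    """A required gait event could not be located in its search window."""


class SynchronizationError(HeelstrikeError):
    """Force and kinematic records do not cover a common time range."""


class InsufficientDataError(HeelstrikeError):
    """Too few samples in a required window (e.g. heel-point median)."""


class ModelAssumptionError(HeelstrikeError):
    """An effective-mass model denominator is non-positive; trial flagged."""


class ConfigError(HeelstrikeError):
    """Invalid simulator or pipeline configuration."""


class RenderError(HeelstrikeError):
    """Synthetic rendering outside the physically representable range."""
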