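"""Exception hierarchy for teamfuse."""


class TeamfuseError(Exception):
    """Base class for all teamfuse errors."""


class ValidationError(TeamfuseError):
    """A value, config entry or manifest field violates its contract."""


class DataError(TeamfuseError):
    """On-disk or in-memory data violates a structural invariant."""


class AlignmentError(TeamfuseError):
    """Streams cannot be brought onto a common clock."""


class FusionError(TeamfuseError):
    """Fusion is impossible with the given sources."""


class ConfigError(TeamfuseError):
    """Unknown or ill-typed configuration key."""
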