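"""Exception hierarchy shared across the pipeline stages."""


class MusicPhysError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(MusicPhysError):
    """An input table or container is missing required columns/fields."""


class ParseError(MusicPhysError):
    """A field could not be parsed into its declared type."""


class DomainError(MusicPhysError, ValueError):
    """A value lies outside its documented domain."""


class ConfigError(MusicPhysError):
    """A configuration value is internally inconsistent or infeasible."""


class InsufficientDataError(MusicPhysError):
    """Too few samples/peaks to carry out the requested estimate."""


class DegenerateChannelError(MusicPhysError):
    """A channel has zero spread and cannot be standardized."""

    def __init__(self, participant_id, measure):
        self.participant_id = participant_id
        self.measure = measure
        super().__init__(
            f"zero spread for participant {participant_id!r}, measure {measure!r}"
        )


class JoinError(MusicPhysError):
    """A key present on one side of a join is missing on the other."""


class BoundsError(MusicPhysError):
    """An event or window exceeds the extent of its recording."""


class SolverError(MusicPhysError):
    """An iterative solver failed to converge; carries diagnostics."""

    def __init__(self, message, diagnostics=None):
        self.diagnostics = diagnostics or {}
        super().__init__(message)
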