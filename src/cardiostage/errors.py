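"""Exception types shared across the pipeline."""


class CardiostageError(Exception):
    """Base class for all package-specific errors."""


class ChannelNotFoundError(CardiostageError):
    """A requested EDF channel is absent from the file."""

    def __init__(self, channel: str, available: list[str]):
        self.channel = channel
        self.available = list(available)
        super().__init__(
            f"channel {channel!r} not found; available channels: {self.available}"
        )


class FormatError(CardiostageError):
    """A file could not be parsed in the expected format."""


class SchemaError(CardiostageError):
    """A stored feature matrix does not match the expected column schema."""


class DegenerateFeatureError(CardiostageError):
    """A feature stream has zero variance and cannot be standardized.

    Recordings raising this are referred to QC for exclusion rather than
    silently repaired.
    """


class ConfigError(CardiostageError):
    """An invalid model, training, or simulator configuration."""


class InputError(CardiostageError):
    """Model input violates its contract (e.g. non-finite values)."""
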