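"""Exception hierarchy; classes map onto the CLI exit-code contract."""


class MarsError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigError(MarsError):
    """Invalid or incomplete configuration (exit code 2)."""

    exit_code = 2


class DataError(MarsError):
    """Malformed or unusable input data (exit code 3)."""

    exit_code = 3


class ProviderError(MarsError):
    """A score provider could not serve a required prediction (exit code 4)."""

    exit_code = 4


class ReferenceError(MarsError):
    """A sequence reference collection is missing or empty (exit code 5)."""

    exit_code = 5
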