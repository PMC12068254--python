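"""Exception hierarchy shared across the package.

CLI exit codes: ConfigError -> 2, DataError -> 3, ComputeError -> 4.
"""


class WallMotionError(Exception):
    """Base class for package errors."""


class ConfigError(WallMotionError):
    """Invalid or incomplete configuration."""


class DataError(WallMotionError):
    """Malformed or inconsistent input data."""


class ComputeError(WallMotionError):
    """A computation stage failed."""
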