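class TrapRescueError(Exception):
    """Base class for package errors."""


class ConfigError(TrapRescueError, ValueError):
    """Invalid configuration or invalid user input (exit code 2 in the CLI)."""


class DataError(TrapRescueError, ValueError):
    """Malformed or inconsistent data encountered at run time."""
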