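"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: configuration errors -> 2,
data/schema errors -> 3, numerical failures -> 4.
"""


class SpinedynError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(SpinedynError):
    """Invalid configuration value or combination (exit code 2)."""


class DataValidationError(SpinedynError):
    """Input data violates the expected schema or contracts (exit code 3)."""


class NumericalError(SpinedynError):
    """Unrecoverable numerical failure, e.g. NaN weights mid-run (exit code 4)."""
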