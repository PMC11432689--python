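"""Exception hierarchy.

Exit codes (used by the CLI): 0 success, 2 configuration error,
3 data/validation error, 4 fit failure.
"""


class SeroraftError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigError(SeroraftError):
    """Invalid pipeline/CLI configuration, detected before any compute."""

    exit_code = 2


class ValidationError(SeroraftError):
    """Invalid data or parameters (bad spec values, inconsistent inputs)."""

    exit_code = 3


class ParseError(ValidationError):
    """Malformed trajectory/table file; message names the frame/line."""


class SchemaError(ValidationError):
    """Topology JSON violating the published schema; message carries a JSON path."""


class FitFailure(SeroraftError):
    """Nonlinear fit did not converge; message carries diagnostics."""

    exit_code = 4
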