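"""Exception hierarchy mapped onto CLI exit codes."""


class GradpainError(Exception):
    """Base class; exit_code drives the CLI exit status."""

    exit_code = 1


class ConfigError(GradpainError):
    """Invalid configuration or specification (exit code 2)."""

    exit_code = 2


class DataError(GradpainError):
    """Invalid or inconsistent input data (exit code 3)."""

    exit_code = 3


class NumericalError(GradpainError):
    """Numerical failure, e.g. rank deficiency or non-convergence (exit code 4)."""

    exit_code = 4
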