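"""Exception hierarchy."""


class NanogebvError(Exception):
    """Base class for all package errors."""


class ConfigError(NanogebvError):
    """Invalid configuration value or unknown configuration key."""


class InputError(NanogebvError):
    """Malformed or inconsistent input data."""


class ParseError(InputError):
    """Unparseable input line; carries a line number where known."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class PredictionError(NanogebvError):
    """Genotype matrix and marker effects cannot be combined."""


class DegenerateInputError(NanogebvError):
    """A statistic is undefined for this input (e.g. zero variance)."""


class BeagleUnavailableError(NanogebvError):
    """The external Beagle executable was not found.

    The built-in haplotype-window imputer (``nanogebv.imputation.impute_ld``)
    provides the same pipeline arm without an external dependency.
    """
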