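"""Exception hierarchy shared across the package.

``ValidationError`` maps to CLI exit code 2 (bad input/config); anything
else escaping a stage maps to exit code 1.
"""


class ValidationError(ValueError):
    """Input, file, or configuration violates a documented precondition."""


class FormatError(ValidationError):
    """A file on disk could not be parsed; carries the offending path."""

    def __init__(self, message: str, path: str | None = None):
        self.path = path
        if path is not None:
            message = f"{path}: {message}"
        super().__init__(message)


class DegenerateInputError(ValueError):
    """Statistic undefined on this input (e.g. zero-variance vector)."""


class CollinearInputError(ValueError):
    """Design matrix is rank deficient; names the collinear columns."""
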