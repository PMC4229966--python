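"""Exception hierarchy shared across the package."""


class BaclopkError(Exception):
    """Base class for all package errors."""


class ParameterError(BaclopkError, ValueError):
    """A structural parameter is outside its physical domain."""


class ConfigurationError(BaclopkError, ValueError):
    """Invalid run configuration, design/model mismatch, or bad option."""


class DataError(BaclopkError, ValueError):
    """Malformed or inconsistent dataset."""


class NumericalError(BaclopkError, RuntimeError):
    """A numerical routine failed to converge or produced invalid output."""


class NCAError(BaclopkError, RuntimeError):
    """Noncompartmental analysis could not be completed for a profile."""

    def __init__(self, reason: str, subject_id: str | None = None):
        self.reason = reason
        self.subject_id = subject_id
        msg = reason if subject_id is None else f"{subject_id}: {reason}"
        super().__init__(msg)


class IdentifiabilityWarning(UserWarning):
    """A parameter appears poorly identified by the data."""
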