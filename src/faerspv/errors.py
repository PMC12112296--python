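"""Exception types shared across the pipeline."""


class FaersPVError(Exception):
    """Base class for all package errors."""


class FormatError(FaersPVError):
    """An input table does not conform to the expected dialect."""

    def __init__(self, role: str, message: str):
        self.role = role
        super().__init__(f"{role}: {message}")


class ConfigError(FaersPVError):
    """Invalid configuration (drug dictionaries, term sets, run config)."""


class UndefinedSignalError(FaersPVError):
    """A disproportionality statistic is undefined for the given table
    (e.g. empty exposure or reference set)."""
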