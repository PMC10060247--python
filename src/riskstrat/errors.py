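"""Structured errors with stable machine-readable codes."""


class RiskstratError(Exception):
    """Base error carrying a stable ``code`` for programmatic handling."""

    def __init__(self, code: str, message: str = ""):
        self.code = code
        super().__init__(f"{code}: {message}" if message else code)


class ConfigError(RiskstratError):
    """Invalid configuration or study specification."""


class DataError(RiskstratError):
    """Invalid or degenerate input data (empty arm, duplicate ids, ...)."""


class EstimationError(RiskstratError):
    """A model fit or effect estimate could not be produced."""
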