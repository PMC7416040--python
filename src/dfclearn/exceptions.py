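"""Exception types shared across the package."""


class DfclearnError(Exception):
    """Base class for all package errors."""


class ConfigError(DfclearnError):
    """Invalid configuration or parameterization (CLI exit code 2)."""


class DataError(DfclearnError):
    """Invalid, inconsistent or insufficient data (CLI exit code 3)."""
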