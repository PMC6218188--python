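"""Shared exception types."""


class RodpathError(Exception):
    """Base class for package errors."""


class ConfigError(RodpathError, ValueError):
    """Malformed configuration or protocol (message names the offending key/line)."""


class FitError(RodpathError, RuntimeError):
    """A model fit failed to converge or its input is infeasible."""
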