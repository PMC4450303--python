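"""Exception hierarchy.

Errors are split into three families so callers (and the CLI exit-code
mapping) can distinguish bad configuration from bad data from a failed
numerical search.
"""


class ArspectError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ArspectError):
    """Parameters are inconsistent with each other or with the data geometry."""


class InvalidInputError(ArspectError):
    """Input data violate a precondition (shape mismatch, non-finite, negative...)."""


class UndefinedMetricError(ArspectError):
    """A metric is mathematically undefined for the given input."""


class SearchFailureError(ArspectError):
    """An iterative parameter search could not bracket or reach its target."""

    def __init__(self, message: str, bracket=None):
        super().__init__(message)
        self.bracket = bracket


class FormatError(ArspectError):
    """A file could not be parsed as one of the supported formats."""
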