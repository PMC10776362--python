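"""Exception hierarchy.

Validation failures (bad configuration, malformed input tables) are kept
distinct from computation failures so callers — the CLI in particular —
can map them to distinct exit codes.
"""


class AirburdenError(Exception):
    """Base class for all package errors."""


class ValidationError(AirburdenError):
    """Invalid configuration or input data (schema, alignment, ranges)."""


class ConfigurationError(ValidationError):
    """A scenario or run configuration violates its invariants."""


class SchemaError(ValidationError):
    """An input table violates the documented file dialect."""


class ComputationError(AirburdenError):
    """A computation could not be carried out on valid-looking inputs."""
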