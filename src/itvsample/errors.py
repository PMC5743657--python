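"""Exception hierarchy shared across the pipeline."""


class ItvSampleError(ValueError):
    """Base class for all package-specific errors."""


class SchemaError(ItvSampleError):
    """A table is structurally unusable (missing column, empty trait list)."""


class ValidationError(ItvSampleError):
    """A table parses but violates the design's invariants (bad factor
    level, non-finite trait value, duplicate leaf)."""


class ConfigError(ItvSampleError):
    """A configuration object is internally inconsistent."""


class AliasingError(ItvSampleError):
    """A model term contributes no estimable degrees of freedom in the
    given design (e.g. a factor constant within the data)."""


class InfeasibleSampleError(ItvSampleError):
    """A requested sampling size cannot be drawn under a strategy's
    constraints; the message names the binding stratum or quadrat."""
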