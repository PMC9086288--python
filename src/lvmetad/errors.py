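"""Exception hierarchy.

Everything raised on purpose derives from LvMetadError so callers (and the
CLI) can distinguish validation failures from genuine bugs.
"""


class LvMetadError(Exception):
    """Base class for all package errors."""


class ParameterError(LvMetadError, ValueError):
    """A numeric parameter violates its precondition."""


class ConfigError(LvMetadError, ValueError):
    """A structured configuration is inconsistent."""


class SchemaError(ConfigError):
    """A config file or table does not match the published schema."""


class GeometryError(LvMetadError, ValueError):
    """A collective-variable mapping is degenerate or out of bounds."""


class RegionError(LvMetadError, ValueError):
    """Integration/selection regions overlap, are empty, or unresolvable."""


class IntegrationError(LvMetadError, RuntimeError):
    """The Langevin integrator met a non-finite force or coordinate."""

    def __init__(self, message: str, step_index: int | None = None):
        if step_index is not None:
            message = f"{message} (at step {step_index})"
        super().__init__(message)
        self.step_index = step_index


class SequencingError(LvMetadError, ValueError):
    """Hill deposition times are non-monotone."""


class ResolutionError(LvMetadError, ValueError):
    """A grid is too coarse to resolve the deposited Gaussians."""


class ParseError(LvMetadError, ValueError):
    """A COLVAR/HILLS/FES text file is malformed."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"{message} (line {line_number})"
        super().__init__(message)
        self.line_number = line_number


class SelectionError(LvMetadError, ValueError):
    """An atom/site selection resolves to nothing."""
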