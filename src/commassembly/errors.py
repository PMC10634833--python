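"""Exception hierarchy shared across the pipeline."""


class CommassemblyError(Exception):
    """Base class for all package errors."""


class FormatError(CommassemblyError):
    """A file could not be parsed under the requested dialect."""


class ValidationError(CommassemblyError):
    """An object violates a structural invariant."""


class ConfigurationError(CommassemblyError):
    """An environment or analysis request is inconsistent with the data."""


class SolverError(CommassemblyError):
    """A linear program did not yield a usable optimum."""


class AnalysisError(CommassemblyError):
    """A statistical operation's preconditions are not met."""
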