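"""Exception hierarchy shared across the package."""


class MethylatorError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(MethylatorError):
    """A file violates its declared table format."""


class DomainError(MethylatorError, ValueError):
    """A numeric argument lies outside its mathematical domain."""


class ConfigurationError(MethylatorError):
    """Inputs are well-formed but inconsistent with the requested analysis."""


class InputError(MethylatorError):
    """Structurally invalid in-memory input (duplicates, empty groups...)."""


class FitError(MethylatorError):
    """A model fit degenerated (collapsed component, vanished weight)."""


class AnalysisError(MethylatorError):
    """A statistical routine cannot produce a meaningful result."""
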