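"""Exception types shared across the pipeline."""


class TorpornaError(Exception):
    """Base class for package errors."""


class ConfigurationError(TorpornaError, ValueError):
    """A specification or configuration object violates its invariants."""


class DegenerateInputError(TorpornaError, ValueError):
    """An input is structurally valid but degenerate (e.g. zero population total)."""
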