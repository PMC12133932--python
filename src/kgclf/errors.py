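"""Exception hierarchy shared across the package."""


class KgclfError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(KgclfError):
    """Schema definition or schema-conformance violation."""


class FusionError(KgclfError):
    """Graphs cannot be fused (e.g. schema mismatch)."""


class ParseError(KgclfError):
    """Malformed record in an input file.

    Carries the 1-based line number when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ConfigurationError(KgclfError):
    """Invalid configuration value (bad regex, empty dictionary, ...)."""


class ExtractionError(KgclfError):
    """An extractor backend failed; carries backend diagnostics."""


class ContractError(KgclfError):
    """A pluggable backend violated its contract (e.g. wrong dimension)."""


class StateError(KgclfError):
    """Operation invoked in an invalid state (untrained model, missing embeddings)."""


class DataError(KgclfError):
    """Invalid training data (label outside label set, ...)."""
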