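"""Exception hierarchy shared across the package."""


class AquatoxError(Exception):
    """Base class for all package-specific errors."""


class EmptyDocumentError(AquatoxError, ValueError):
    """Raised when a document with no text is submitted for processing."""


class SchemaError(AquatoxError, ValueError):
    """Raised when a molecule table is missing required columns."""


class EmptyDatasetError(AquatoxError, ValueError):
    """Raised when no valid molecule rows survive loading."""


class FeatureError(AquatoxError, ValueError):
    """Raised when a required descriptor or feature is unavailable."""


class ProviderError(AquatoxError, ValueError):
    """Raised when a descriptor provider cannot serve a requested name."""


class UnitError(AquatoxError, ValueError):
    """Raised on inconsistent scale/unit declarations in model composition."""


class UndefinedCorrelationError(AquatoxError, ValueError):
    """Raised when a rank correlation is undefined (constant input or n < 3)."""
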