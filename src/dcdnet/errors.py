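"""Package-wide exception types."""

from .nn.functional import ShapeError

__all__ = ["ConfigurationError", "ValidationError", "AssemblyError", "ShapeError"]


class ConfigurationError(ValueError):
    """Invalid or unknown configuration value (backbone name, hyperparameter)."""


class ValidationError(ValueError):
    """Data fails a contract (non-binary mask, unknown lesion type, duplicate id)."""


class AssemblyError(RuntimeError):
    """An intermediate feature map deviates from the layer-ledger contract."""
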