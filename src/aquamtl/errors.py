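"""Structured exceptions raised across the package."""


class AquaMTLError(Exception):
    """Base class for all package errors."""


class DataError(AquaMTLError):
    """Malformed, empty, or inconsistent panel / window data."""


class ConfigError(AquaMTLError):
    """Invalid run, model, or generator configuration."""


class TrainingError(AquaMTLError):
    """Optimization failure (e.g. non-finite loss)."""
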