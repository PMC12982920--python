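"""Exception hierarchy for slskit."""


class SLSKitError(Exception):
    """Base class for all slskit errors."""


class ConfigError(SLSKitError):
    """Invalid configuration (counts, fractions, correlation structure, folds...)."""


class SchemaError(SLSKitError):
    """A required landmark or feature column is missing or malformed."""


class DegenerateGeometryError(SLSKitError):
    """Coincident landmarks make an angle undefined."""


class SequenceQualityError(SLSKitError):
    """Too many low-visibility frames, or a visibility gap too long to bridge."""


class InvalidTrialError(SLSKitError):
    """A participant has no valid repetition to aggregate."""
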