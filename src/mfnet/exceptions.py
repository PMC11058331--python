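"""Exception hierarchy for the mfnet toolkit."""


class MFNetError(Exception):
    """Base class for all toolkit errors."""


class InvalidInputError(MFNetError, ValueError):
    """An operation received inputs violating its preconditions."""


class RangeError(MFNetError, ValueError):
    """A scalar argument lies outside its documented range."""


class ConfigError(MFNetError, ValueError):
    """A configuration object is internally inconsistent."""


class ManifestError(MFNetError, ValueError):
    """A dataset manifest is malformed or references missing files."""


class GenerationError(MFNetError, RuntimeError):
    """Phantom generation failed to produce feasible geometry."""


class TrainingDivergenceError(MFNetError, RuntimeError):
    """A non-finite loss or gradient was encountered during training."""
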