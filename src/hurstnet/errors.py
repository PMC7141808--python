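"""Exception hierarchy."""


class HurstnetError(Exception):
    """Base class for all package errors."""


class ParameterError(HurstnetError, ValueError):
    """A parameter is outside its valid domain."""


class DegenerateInputError(HurstnetError, ValueError):
    """Input data admits no meaningful answer (constant series, zero range...)."""


class UndefinedFitError(HurstnetError, ValueError):
    """A regression/fit has no solution on the given data."""


class TrainingError(HurstnetError, RuntimeError):
    """Network training failed (non-finite loss)."""


class ModelFormatError(HurstnetError, RuntimeError):
    """A saved model file is corrupt, incompatible or fails verification."""
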