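"""Exception hierarchy used across the pipeline."""


class ScsemError(Exception):
    """Base class for all package errors."""


class InputFormatError(ScsemError):
    """A count-matrix file is missing, malformed, or inconsistent."""


class DegenerateInputError(ScsemError):
    """The data collapses under a preprocessing rule (e.g. zero genes left)."""


class ConfigError(ScsemError):
    """An invalid run/simulation configuration."""


class CapacityError(ScsemError):
    """The cell count exceeds what the dense N x N self-expressive matrix allows."""


class TrainingDivergenceError(ScsemError):
    """Non-finite loss or activations during optimization."""


class CalibrationError(ScsemError):
    """Dropout calibration target outside the achievable range."""
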