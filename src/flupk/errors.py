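"""Exception and warning types used across flupk."""


class ValidationError(ValueError):
    """Raised when an input violates a physiologic or structural constraint."""


class ConfigError(ValueError):
    """Raised for incomplete or inconsistent model/trial configuration."""


class DatasetError(ValueError):
    """Raised for malformed longitudinal datasets."""


class ConvergenceError(RuntimeError):
    """Raised when the MAP optimizer fails to converge from every start."""


class AgeExtrapolationWarning(UserWarning):
    """Emitted when a covariate model is evaluated outside its validated age range."""
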