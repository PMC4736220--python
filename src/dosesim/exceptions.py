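"""Exception and warning types shared across the package."""


class DosesimError(Exception):
    """Base class for all package-specific errors."""


class InsufficientDataError(DosesimError, ValueError):
    """Too few readings to compute the requested statistic."""


class MissingDataError(DosesimError, ValueError):
    """A required reading (e.g. a phantom location) is absent."""


class ConfigurationError(DosesimError, ValueError):
    """Layout / error-model configuration is inconsistent."""


class FitRejectedError(DosesimError, ValueError):
    """A fitted read-out RSD model predicts non-positive RSD in its range."""


class NegativeDoseWarning(UserWarning):
    """A background-corrected dose came out negative and was clamped to 0."""


class ExtrapolationWarning(UserWarning):
    """A read-out RSD model was evaluated outside its fitted value range."""
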