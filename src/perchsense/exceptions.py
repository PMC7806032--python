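"""Exception and warning types used across the package."""


class PerchsenseError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(PerchsenseError, ValueError):
    """An argument violates an operation's precondition."""


class CapacityError(PerchsenseError):
    """A requested simulation would exceed the configured memory budget."""


class UndefinedCorrelationError(PerchsenseError):
    """Cross-correlation is undefined (zero-variance input)."""


class UndefinedVafError(PerchsenseError):
    """VAF is undefined because the reference signal has zero variance."""


class IllConditionedFitError(PerchsenseError):
    """A subspace-identification step was too ill-conditioned to solve."""


class DegenerateDataError(PerchsenseError):
    """Data carry no usable signal for the requested operation."""


class UnstableSystemWarning(UserWarning):
    """The discretized mechanical chain has a non-contractive eigenvalue."""


class NoDominantResonanceWarning(UserWarning):
    """The spectral peak is not prominent; the resonance estimate is weak."""


class OverlappingWindowsWarning(UserWarning):
    """Bootstrap windows overlap; downstream t-tests are anti-conservative."""
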