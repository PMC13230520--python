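"""Exception types shared across the package."""


class CfdynError(Exception):
    """Base class for package-specific errors."""


class DivergedStateError(CfdynError):
    """A trajectory escaped toward infinity (state norm above the guard).

    Carries ``step``, the discrete step index at which divergence was
    detected (``None`` when the offending step is unknown).
    """

    def __init__(self, message: str, step: int | None = None):
        super().__init__(message)
        self.step = step


class DegenerateLikelihoodError(CfdynError):
    """An observation-noise variance of zero makes the likelihood a point mass."""


class UndefinedThresholdError(CfdynError):
    """The closed-form chaos threshold is undefined for these parameters."""
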