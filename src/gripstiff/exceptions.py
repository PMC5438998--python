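"""Exception hierarchy for the gripstiff pipeline."""


class GripstiffError(Exception):
    """Base class for all package errors."""


class ConfigError(GripstiffError):
    """Invalid or inconsistent configuration (e.g. range with min > max)."""


class GenerationError(GripstiffError):
    """Synthetic trial cannot be generated under the configured constraints."""


class InputError(GripstiffError):
    """Malformed or insufficient input data."""


class DetectionError(GripstiffError):
    """No pre-perturbation quiet window satisfies the SD criterion.

    Carries the minimal window SD found so callers can judge how far off
    the configured threshold is.
    """

    def __init__(self, message: str, min_sd: float | None = None):
        super().__init__(message)
        self.min_sd = min_sd


class NormalizationError(GripstiffError):
    """Degenerate normalization (zero maximum or zero SD), names the electrode."""


class FitError(GripstiffError):
    """Regression design is rank deficient or otherwise unusable."""
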