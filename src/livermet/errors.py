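"""Exception and warning types shared across the package."""


class LivermetError(Exception):
    """Base class for all package-specific errors."""


class DegenerateDesignError(LivermetError):
    """Calibration design cannot identify a line (fewer than 2 distinct cell counts)."""


class NonMonotoneCalibrationError(LivermetError):
    """Fitted calibration slope is not positive; signal does not increase with cells."""


class UndefinedCorrelationError(LivermetError):
    """Pearson correlation is undefined (constant input vector or too few points)."""


class ModalityMismatchError(LivermetError):
    """A curve of the wrong optical modality was supplied."""


class UndefinedDoublingTimeError(LivermetError):
    """Doubling time is undefined (colony indistinguishable from its founder)."""


class InconsistentBurdenError(LivermetError):
    """Burden bookkeeping is internally inconsistent (e.g. more tumors than injected cells)."""


class PlacementError(LivermetError):
    """Colonies could not be placed in the image field under the separation constraint."""


class CalibrationWarning(UserWarning):
    """Non-fatal calibration issue, e.g. a signal below the fitted background."""
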