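"""Linear calibration between plated cell number and optical signal.

Cell-number quantification throughout the package rests on a standard-curve
experiment: known cell numbers are plated, their bioluminescent or fluorescent
signal is read, and an ordinary least-squares line ``signal = slope * cells +
intercept`` is fitted. The inverse map converts any measured signal into an
inferred cell number. Both modalities (luciferase photon flux and fluorophore
radiant efficiency) are handled by the same machinery; the modality travels
with the curve so that downstream code can reject a mismatched one.

The regression keeps an intercept: empty (0-cell) wells are part of the plated
design and carry real background signal. Replicates are pooled, not averaged,
so the correlation coefficient reflects the replicate variance structure.
"""

from __future__ import annotations

import enum
import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .errors import (
    CalibrationWarning,
    DegenerateDesignError,
    NonMonotoneCalibrationError,
    UndefinedCorrelationError,
)

__all__ = [
    "Modality",
    "CalibrationPoint",
    "CalibrationCurve",
    "fit_calibration",
    "cells_from_signal",
    "predict_signal",
    "pearson_correlation",
]


class Modality(str, enum.Enum):
    """Optical readout modality of a measurement or curve."""

    LUMINESCENCE = "luminescence"
    FLUORESCENCE = "fluorescence"


@dataclass(frozen=True)
class CalibrationPoint:
    """One well of a calibration plate.

    Parameters
    ----------
    cell_count
        Number of cells plated in the well (>= 0).
    signal
        Measured optical signal: photon flux (p/sec/cm^2/sr) for luminescence,
        radiant efficiency for fluorescence. Must be >= 0.
    modality
        Readout modality of this measurement.
    replicate
        Replicate index within the plated density (0-based).
    """

    cell_count: float
    signal: float
    modality: Modality
    replicate: int = 0

    def __post_init__(self) -> None:
        if self.cell_count < 0:
            raise ValueError(f"cell_count must be >= 0, got {self.cell_count}")
        if self.signal < 0:
            raise ValueError(f"signal must be >= 0, got {self.signal}")
        object.__setattr__(self, "modality", Modality(self.modality))


@dataclass(frozen=True)
class CalibrationCurve:
    """Fitted linear map between cell number and optical signal.

    ``signal = slope * cells + intercept`` with ``slope`` in signal units per
    cell. ``pearson_r`` is the sample Pearson coefficient over all pooled
    points and ``n_points`` the number of wells that entered the fit.
    """

    modality: Modality
    slope: float
    intercept: float
    pearson_r: float
    n_points: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "modality", Modality(self.modality))
        if not np.isfinite(self.pearson_r):
            raise ValueError("pearson_r must be finite")
        if self.n_points < 3:
            raise ValueError("a calibration curve needs at least 3 points")
        if self.slope <= 0:
            raise NonMonotoneCalibrationError(
                f"calibration slope must be > 0, got {self.slope:g}"
            )

    def to_json(self, path: str | Path) -> None:
        """Serialize the curve to a JSON file."""
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["modality"] = self.modality.value
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationCurve":
        return cls(
            modality=Modality(d["modality"]),
            slope=float(d["slope"]),
            intercept=float(d["intercept"]),
            pearson_r=float(d["pearson_r"]),
            n_points=int(d["n_points"]),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationCurve":
        return cls.from_dict(json.loads(Path(path).read_text()))


def fit_calibration(points: Iterable[CalibrationPoint]) -> CalibrationCurve:
    """Fit the standard curve by ordinary least squares of signal on cells.

    All points must share one modality; replicates are pooled. Raises
    :class:`DegenerateDesignError` if fewer than 2 distinct cell counts are
    present and :class:`NonMonotoneCalibrationError` if the fitted slope is
    not positive.
    """
    pts = list(points)
    if len(pts) < 3:
        raise DegenerateDesignError(
            f"need at least 3 calibration points, got {len(pts)}"
        )
    modalities = {p.modality for p in pts}
    if len(modalities) != 1:
        raise ValueError(f"mixed modalities in calibration points: {modalities}")
    (modality,) = modalities

    cells = np.array([p.cell_count for p in pts], dtype=float)
    signal = np.array([p.signal for p in pts], dtype=float)
    if np.unique(cells).size < 2:
        raise DegenerateDesignError(
            "calibration design is degenerate: need >= 2 distinct cell counts"
        )

    fit = stats.linregress(cells, signal)
    if fit.slope <= 0:
        raise NonMonotoneCalibrationError(
            f"fitted calibration slope is {fit.slope:g} <= 0"
        )
    return CalibrationCurve(
        modality=modality,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        pearson_r=float(fit.rvalue),
        n_points=len(pts),
    )


def predict_signal(curve: CalibrationCurve, cells: float) -> float:
    """Expected signal for a given cell number under the fitted line."""
    if cells < 0:
        raise ValueError(f"cells must be >= 0, got {cells}")
    return curve.slope * cells + curve.intercept


def cells_from_signal(curve: CalibrationCurve, signal: float) -> float:
    """Invert the standard curve: infer cell number from a measured signal.

    Signals below the fitted background (intercept) are clamped to 0 cells
    with a :class:`CalibrationWarning` rather than raising.
    """
    if signal < 0:
        raise ValueError(f"signal must be >= 0, got {signal}")
    cells = (signal - curve.intercept) / curve.slope
    if cells < 0:
        warnings.warn(
            f"signal {signal:g} is below the fitted background "
            f"{curve.intercept:g}; clamping inferred cells to 0",
            CalibrationWarning,
            stacklevel=2,
        )
        return 0.0
    return cells


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson product-moment correlation coefficient.

    Raises :class:`UndefinedCorrelationError` for constant vectors or fewer
    than 3 paired observations.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape:
        raise ValueError(f"length mismatch: {xa.shape} vs {ya.shape}")
    if xa.size < 3:
        raise UndefinedCorrelationError("need at least 3 paired observations")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise UndefinedCorrelationError("correlation undefined for a constant vector")
    return float(stats.pearsonr(xa, ya).statistic)
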