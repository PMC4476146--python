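"""Liver tumor burden metrics: colonizing fraction, doubling time, volumes.

The experimental model is intrasplenic injection of a known dose of labeled
tumor cells; cells reach the liver via the portal circulation and a small
fraction of them found macroscopic colonies. Two clone-level parameters
summarize metastatic potential:

* the colonizing fraction ``Fc`` — tumors counted in the liver divided by
  cells injected, i.e. the per-cell probability of founding a colony;
* the doubling time ``Td`` — hours per population doubling, inferred from a
  colony's final cell number N and the elapsed growth time t under
  exponential growth from a single founding cell:
  ``Td = t * ln 2 / ln N`` and ``divisions = log2 N``.

Cell numbers per colony come from the fluorescence standard curve
(:mod:`livermet.calibration`); macroscopic volumes assume spherical colonies.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import NamedTuple, Optional, Sequence

import numpy as np

from .calibration import CalibrationCurve, Modality, cells_from_signal
from .errors import (
    InconsistentBurdenError,
    ModalityMismatchError,
    UndefinedDoublingTimeError,
)

__all__ = [
    "Colony",
    "LiverBurden",
    "ClonePhenotype",
    "GrowthScenario",
    "colonizing_fraction",
    "doubling_time",
    "n_divisions",
    "sphere_volume",
    "total_burden",
    "BurdenTotals",
    "colony_cells",
    "clone_phenotype",
    "classify_phenotype",
]


@dataclass(frozen=True)
class Colony:
    """One metastatic focus in a harvested liver.

    ``fluor_signal`` is the colony's integrated ex vivo radiant efficiency;
    ``diameter_mm`` the macroscopic diameter where measured; ``cell_count``
    the inferred number of cells (filled by :func:`colony_cells` or by the
    simulator). ``position`` optionally records the (row, col) pixel centroid
    of the colony in a rendered image, used as ground truth for detection.
    """

    fluor_signal: float
    diameter_mm: Optional[float] = None
    cell_count: Optional[float] = None
    position: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        if self.fluor_signal < 0:
            raise ValueError("fluor_signal must be >= 0")
        if self.diameter_mm is not None and self.diameter_mm <= 0:
            raise ValueError("diameter_mm must be > 0 when present")
        if self.cell_count is not None and self.cell_count < 1:
            raise ValueError("a detected colony has cell_count >= 1")

    @property
    def volume_mm3(self) -> Optional[float]:
        """Spherical volume from the macroscopic diameter, if measured."""
        if self.diameter_mm is None:
            return None
        return sphere_volume(self.diameter_mm)


@dataclass(frozen=True)
class LiverBurden:
    """All colonies of one mouse liver plus the injection metadata."""

    mouse_id: str
    clone_id: str
    n_injected: int
    harvest_time: float  # hours since injection
    colonies: tuple[Colony, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.n_injected <= 0:
            raise ValueError("n_injected must be > 0")
        if self.harvest_time <= 0:
            raise ValueError("harvest_time must be > 0")
        object.__setattr__(self, "colonies", tuple(self.colonies))
        if len(self.colonies) > self.n_injected:
            raise InconsistentBurdenError(
                f"{len(self.colonies)} colonies from {self.n_injected} injected cells"
            )

    @property
    def n_tumors(self) -> int:
        return len(self.colonies)

    @property
    def total_volume_mm3(self) -> float:
        return sum(c.volume_mm3 or 0.0 for c in self.colonies)

    @property
    def total_fluor(self) -> float:
        return sum(c.fluor_signal for c in self.colonies)


class GrowthScenario(enum.Enum):
    """Qualitative metastasis-development scenario from the (Fc, Td) plane."""

    MANY_SMALL = "many_small"  # high Fc, slow growth (polymetastatic, small foci)
    FEW_LARGE = "few_large"    # low Fc, fast growth (few large foci)
    FEW_SMALL = "few_small"    # low Fc, slow growth (oligometastatic-like)
    MANY_LARGE = "many_large"  # high Fc, fast growth (not observed experimentally)


@dataclass(frozen=True)
class ClonePhenotype:
    """Clone-level summary of colonization and growth across mice.

    ``fc_*`` aggregate per-mouse colonizing fractions; ``td_*`` aggregate
    per-colony doubling times pooled within the clone; ``n_av`` is the mean
    number of cells per colony at harvest and ``divisions_mean = log2(n_av)``.
    Dispersion is the sample standard deviation (n-1); NaN where n < 2.
    """

    clone_id: str
    fc_mean: float
    fc_sd: float
    td_mean: float
    td_sd: float
    n_av: float
    divisions_mean: float
    n_mice: int


def colonizing_fraction(n_tumors: int, n_injected: int) -> float:
    """Fraction of injected cells that founded a macroscopic liver colony."""
    if n_injected <= 0:
        raise ValueError(f"n_injected must be > 0, got {n_injected}")
    if n_tumors < 0:
        raise ValueError(f"n_tumors must be >= 0, got {n_tumors}")
    if n_tumors > n_injected:
        raise InconsistentBurdenError(
            f"n_tumors ({n_tumors}) exceeds n_injected ({n_injected})"
        )
    return n_tumors / n_injected


def doubling_time(cell_count: float, elapsed: float) -> float:
    """Doubling time (hours) from final cell number and elapsed growth time.

    Assumes exponential growth from one founding cell with no lag:
    ``N = 2**(t/Td)`` hence ``Td = t * ln2 / ln N``. Undefined for colonies
    of fewer than 2 cells (no completed division).
    """
    if elapsed <= 0:
        raise ValueError(f"elapsed must be > 0 hours, got {elapsed}")
    if cell_count < 2:
        raise UndefinedDoublingTimeError(
            f"cell_count {cell_count:g} < 2: colony indistinguishable from founder"
        )
    return elapsed * math.log(2) / math.log(cell_count)


def n_divisions(cell_count: float) -> float:
    """Number of completed cell divisions, log2 of the final cell number."""
    if cell_count < 1:
        raise ValueError(f"cell_count must be >= 1, got {cell_count}")
    return math.log2(cell_count)


def sphere_volume(diameter: float) -> float:
    """Volume (mm^3) of a sphere of the given diameter (mm)."""
    if diameter <= 0:
        raise ValueError(f"diameter must be > 0, got {diameter}")
    return math.pi * diameter**3 / 6.0


class BurdenTotals(NamedTuple):
    total_volume: float
    total_fluor: float
    n_tumors: int


def total_burden(burden: LiverBurden) -> BurdenTotals:
    """Whole-liver totals: summed volume, summed fluorescence, tumor count."""
    return BurdenTotals(burden.total_volume_mm3, burden.total_fluor, burden.n_tumors)


def colony_cells(curve: CalibrationCurve, colony: Colony) -> Colony:
    """Fill a colony's cell number from its fluorescence via the standard curve.

    Requires the fluorescence curve. Detected colonies are floored at one
    cell so that faint foci keep Fc and per-colony statistics well defined.
    """
    if curve.modality is not Modality.FLUORESCENCE:
        raise ModalityMismatchError(
            f"cell-number inference needs the fluorescence curve, got {curve.modality.value}"
        )
    cells = max(1.0, cells_from_signal(curve, colony.fluor_signal))
    return replace(colony, cell_count=cells)


def _sample_sd(values: Sequence[float]) -> float:
    return float(np.std(values, ddof=1)) if len(values) > 1 else float("nan")


def clone_phenotype(
    burdens: Sequence[LiverBurden],
    curve: CalibrationCurve,
    sample_size: int = 5,
    seed: int | None = None,
    all_colonies: bool = False,
) -> ClonePhenotype:
    """Summarize one clone's colonization and growth phenotype across mice.

    Fc is computed per mouse and aggregated as mean +/- SD across mice. For
    growth, up to ``sample_size`` representative colonies per liver are drawn
    uniformly without replacement (seeded; ``all_colonies=True`` uses every
    colony), converted to cell numbers via the fluorescence curve, and their
    doubling times pooled within the clone. ``n_av`` averages over the same
    sampled colonies.
    """
    if not burdens:
        raise ValueError("need at least one liver burden")
    clone_ids = {b.clone_id for b in burdens}
    if len(clone_ids) != 1:
        raise ValueError(f"mixed clone_ids: {sorted(clone_ids)}")
    (clone_id,) = clone_ids

    fcs = [colonizing_fraction(b.n_tumors, b.n_injected) for b in burdens]

    rng = np.random.default_rng(seed)
    cells_per_colony: list[float] = []
    tds: list[float] = []
    for b in burdens:
        if not b.colonies:
            continue
        if all_colonies or len(b.colonies) <= sample_size:
            chosen = list(b.colonies)
        else:
            idx = rng.choice(len(b.colonies), size=sample_size, replace=False)
            chosen = [b.colonies[i] for i in sorted(idx)]
        for col in chosen:
            n = colony_cells(curve, col).cell_count
            cells_per_colony.append(n)
            if n >= 2:
                tds.append(doubling_time(n, b.harvest_time))

    if cells_per_colony:
        n_av = float(np.mean(cells_per_colony))
        divisions_mean = math.log2(n_av)
    else:
        n_av = float("nan")
        divisions_mean = float("nan")
    td_mean = float(np.mean(tds)) if tds else float("nan")

    return ClonePhenotype(
        clone_id=clone_id,
        fc_mean=float(np.mean(fcs)),
        fc_sd=_sample_sd(fcs),
        td_mean=td_mean,
        td_sd=_sample_sd(tds),
        n_av=n_av,
        divisions_mean=divisions_mean,
        n_mice=len(burdens),
    )


def classify_phenotype(
    ph: ClonePhenotype,
    fc_threshold: float = 2e-5,
    td_threshold: float = 24.5,
) -> GrowthScenario:
    """Place a clone in one of four (Fc, Td) scenarios.

    High Fc with slow growth yields many small foci; low Fc with fast growth
    yields few large foci; low Fc with slow growth is the oligometastatic-like
    pattern; high Fc with fast growth is labeled explicitly although it was
    not observed experimentally. Thresholds are explicit parameters.
    """
    if fc_threshold <= 0 or td_threshold <= 0:
        raise ValueError("classification thresholds must be positive")
    high_fc = ph.fc_mean >= fc_threshold
    fast = ph.td_mean < td_threshold
    if high_fc and not fast:
        return GrowthScenario.MANY_SMALL
    if not high_fc and fast:
        return GrowthScenario.FEW_LARGE
    if not high_fc and not fast:
        return GrowthScenario.FEW_SMALL
    return GrowthScenario.MANY_LARGE
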