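"""Stochastic generative model of intrasplenic-injection liver colonization.

This module is the synthetic stand-in for the animal experiment. Its model:

* **Seeding** — each of the ``n_injected`` cells independently founds a liver
  colony with probability ``fc``, so the colony count per mouse is
  Binomial(n_injected, fc). No Poisson approximation is used; the dose is
  finite and ``fc <= 1`` stays enforceable.
* **Outgrowth** — every colony grows exponentially from exactly one founding
  cell. Clone-to-clone growth heterogeneity is modeled by drawing each
  colony's doubling time from a lognormal with mean ``td_mean`` and
  coefficient of variation ``td_cv``; the colony reaches
  ``N = 2**(harvest_time / Td)`` cells at harvest.
* **Readout** — optical signal is linear in cell number through a
  :class:`~livermet.calibration.CalibrationCurve`, corrupted by multiplicative
  lognormal measurement noise of CV ``noise_cv`` (optical signals are positive
  and heteroscedastic). Macroscopic diameter follows from cell number under a
  constant packing density: ``d = (6 N / (pi * rho))**(1/3)``.

Reproducibility contract: a single integer seed, with hierarchical substreams
``SeedSequence((seed, stream, mouse_index))`` where stream 0 is the harvested
cohort and stream 1 the longitudinal imaging series. Identical seeds give
bit-identical cohorts; the scheme is part of the public API and stable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .burden import Colony, LiverBurden
from .calibration import CalibrationCurve, CalibrationPoint, Modality, predict_signal

__all__ = [
    "SimParams",
    "Cohort",
    "DEFAULT_FLUOR_CURVE",
    "DEFAULT_LUM_CURVE",
    "PLATE_DENSITIES",
    "HOURS_PER_WEEK",
    "scenario_params",
    "SCENARIOS",
    "simulate_liver",
    "simulate_cohort",
    "simulate_longitudinal",
    "generate_calibration_plate",
    "write_fixtures",
    "read_fixtures",
]

HOURS_PER_WEEK = 168.0

#: Plated densities of the in vitro standard-curve experiment (cells/well).
PLATE_DENSITIES = (0, 1_000, 10_000, 20_000, 30_000, 50_000, 70_000, 90_000, 100_000)

# Default noise-free calibration curves used by the simulator when none is
# supplied. Slopes/intercepts are representative instrument scales (radiant
# efficiency per cell; photon flux per cell); only the linear form matters to
# the analysis, which always re-estimates cell numbers through a fitted curve.
DEFAULT_FLUOR_CURVE = CalibrationCurve(
    modality=Modality.FLUORESCENCE, slope=170.0, intercept=2.0e4,
    pearson_r=1.0, n_points=27,
)
DEFAULT_LUM_CURVE = CalibrationCurve(
    modality=Modality.LUMINESCENCE, slope=1.3e4, intercept=1.0e5,
    pearson_r=1.0, n_points=27,
)


@dataclass(frozen=True)
class SimParams:
    """Generative parameters of the colonization model for one clone.

    Defaults mirror the experimental design: a dose of 2.0e6 cells injected
    per mouse, 5% inter-colony doubling-time CV (consistent with the small
    observed Td dispersions), 5% multiplicative measurement noise, and a
    packing density of 1e6 cells/mm^3 (typical solid-tumor cellularity; it
    only links cell number to macroscopic diameter).
    """

    clone_id: str
    fc: float
    td_mean: float  # hours
    harvest_time: float  # hours since injection
    n_injected: int = 2_000_000
    td_cv: float = 0.05
    noise_cv: float = 0.05
    packing_density: float = 1.0e6  # cells/mm^3
    fluor_curve: CalibrationCurve = DEFAULT_FLUOR_CURVE
    lum_curve: CalibrationCurve = DEFAULT_LUM_CURVE
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fc <= 1.0:
            raise ValueError(f"fc must be in [0, 1], got {self.fc}")
        if self.td_mean <= 0:
            raise ValueError("td_mean must be > 0")
        if self.td_cv < 0 or self.noise_cv < 0:
            raise ValueError("td_cv and noise_cv must be >= 0")
        if self.harvest_time <= 0:
            raise ValueError("harvest_time must be > 0")
        if self.packing_density <= 0:
            raise ValueError("packing_density must be > 0")
        if self.n_injected <= 0:
            raise ValueError("n_injected must be > 0")
        if self.fluor_curve.modality is not Modality.FLUORESCENCE:
            raise ValueError("fluor_curve must have fluorescence modality")
        if self.lum_curve.modality is not Modality.LUMINESCENCE:
            raise ValueError("lum_curve must have luminescence modality")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["fluor_curve"] = self.fluor_curve.to_dict()
        d["lum_curve"] = self.lum_curve.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimParams":
        d = dict(d)
        d["fluor_curve"] = CalibrationCurve.from_dict(d["fluor_curve"])
        d["lum_curve"] = CalibrationCurve.from_dict(d["lum_curve"])
        return cls(**d)


@dataclass(frozen=True)
class Cohort:
    """Simulated mice of one clone plus the parameters that generated them."""

    params: SimParams
    burdens: tuple[LiverBurden, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "burdens", tuple(self.burdens))
        for b in self.burdens:
            if b.clone_id != self.params.clone_id:
                raise ValueError("burden clone_id does not match cohort params")


# Scenario presets on the (Fc, Td) plane. P1/P2/O1 carry the experimentally
# estimated values (P-clone cohorts harvested at 3 weeks, O clones at 4);
# no point estimates exist for O2, so it carries representative
# oligometastatic values: low Fc, slow growth.
SCENARIOS: dict[str, dict] = {
    "P1": dict(fc=8.2e-5, td_mean=26.5, harvest_time=504.0),
    "P2": dict(fc=1.1e-5, td_mean=22.7, harvest_time=504.0),
    "O1": dict(fc=6.0e-6, td_mean=26.5, harvest_time=672.0),
    "O2": dict(fc=5.0e-6, td_mean=27.0, harvest_time=672.0),
}


def scenario_params(name: str, seed: int = 0, **overrides) -> SimParams:
    """SimParams preset for one of the characterized clones (P1, P2, O1, O2)."""
    if name not in SCENARIOS:
        raise KeyError(f"unknown scenario {name!r}; choose from {sorted(SCENARIOS)}")
    kwargs = dict(SCENARIOS[name], clone_id=name, seed=seed)
    kwargs.update(overrides)
    return SimParams(**kwargs)


def _lognormal_factors(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Multiplicative lognormal factors with mean 1 and the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv * cv)
    mu = -0.5 * sigma2
    return rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=size)


def _draw_tds(rng: np.random.Generator, params: SimParams, size: int) -> np.ndarray:
    """Per-colony doubling times: lognormal, mean td_mean, CV td_cv."""
    return params.td_mean * _lognormal_factors(rng, params.td_cv, size)


def _mouse_rng(params: SimParams, stream: int, mouse_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence((params.seed, stream, mouse_index))
    )


def simulate_liver(params: SimParams, mouse_index: int) -> LiverBurden:
    """Simulate one mouse liver at harvest. Deterministic given (seed, mouse_index)."""
    rng = _mouse_rng(params, 0, mouse_index)
    n_col = int(rng.binomial(params.n_injected, params.fc))
    tds = _draw_tds(rng, params, n_col)
    cells = np.exp2(params.harvest_time / tds)
    noise = _lognormal_factors(rng, params.noise_cv, n_col)
    signals = np.array(
        [predict_signal(params.fluor_curve, n) for n in cells]
    ) * noise
    diameters = np.cbrt(6.0 * cells / (np.pi * params.packing_density))
    colonies = tuple(
        Colony(
            fluor_signal=float(s),
            diameter_mm=float(d),
            cell_count=float(n),
        )
        for s, d, n in zip(signals, diameters, cells)
    )
    return LiverBurden(
        mouse_id=f"{params.clone_id}_m{mouse_index + 1}",
        clone_id=params.clone_id,
        n_injected=params.n_injected,
        harvest_time=params.harvest_time,
        colonies=colonies,
    )


def simulate_cohort(params: SimParams, n_mice: int) -> Cohort:
    """Simulate a cohort of independent mice via per-mouse seed substreams."""
    if n_mice < 1:
        raise ValueError(f"n_mice must be >= 1, got {n_mice}")
    burdens = tuple(simulate_liver(params, i) for i in range(n_mice))
    return Cohort(params=params, burdens=burdens)


def simulate_longitudinal(
    params: SimParams,
    weeks: Sequence[int],
    n_mice: int = 3,
) -> pd.DataFrame:
    """Weekly whole-body bioluminescence for a simulated cohort.

    Each mouse's colony set (count and per-colony doubling times) is drawn
    once; at week ``w`` every colony is evaluated at ``t = 168*w`` hours and
    the whole-liver photon flux is the luminescence-curve prediction for the
    summed cells, times one multiplicative noise factor per measurement.
    Returns a tidy table with columns ``mouse_id, week, total_flux``.
    """
    weeks = list(weeks)
    if not weeks or any(w <= 0 for w in weeks):
        raise ValueError("weeks must be a nonempty list of positive integers")
    rows = []
    for i in range(n_mice):
        rng = _mouse_rng(params, 1, i)
        n_col = int(rng.binomial(params.n_injected, params.fc))
        tds = _draw_tds(rng, params, n_col)
        noise = _lognormal_factors(rng, params.noise_cv, len(weeks))
        for w, eta in zip(weeks, noise):
            t = HOURS_PER_WEEK * w
            total_cells = float(np.exp2(t / tds).sum()) if n_col else 0.0
            flux = predict_signal(params.lum_curve, total_cells) * eta
            rows.append(
                {"mouse_id": f"{params.clone_id}_m{i + 1}", "week": w,
                 "total_flux": flux}
            )
    return pd.DataFrame(rows, columns=["mouse_id", "week", "total_flux"])


def generate_calibration_plate(
    true_slope: float,
    true_intercept: float,
    densities: Sequence[int] = PLATE_DENSITIES,
    replicates: int = 3,
    noise_cv: float = 0.05,
    seed: int = 0,
    modality: Modality = Modality.FLUORESCENCE,
) -> list[CalibrationPoint]:
    """Synthetic calibration plate: a linear response with multiplicative noise.

    Emulates plating the standard densities in triplicate and reading each
    well once: ``signal = (slope*cells + intercept) * lognormal(1, noise_cv)``.
    """
    if true_slope <= 0:
        raise ValueError("true_slope must be > 0")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    densities = list(densities)
    if not densities:
        raise ValueError("densities must be nonempty")
    rng = np.random.default_rng(seed)
    points = []
    for cells in densities:
        factors = _lognormal_factors(rng, noise_cv, replicates)
        for rep, eta in enumerate(factors):
            signal = (true_slope * cells + true_intercept) * float(eta)
            points.append(
                CalibrationPoint(
                    cell_count=cells, signal=signal, modality=modality, replicate=rep
                )
            )
    return points


# ---------------------------------------------------------------------------
# Fixture I/O: delimited-text cohort round trip


def write_fixtures(cohort: Cohort, directory: str | Path) -> dict[str, Path]:
    """Write a cohort as plain-text fixtures: colonies.csv, mice.csv, params.json.

    The colonies table carries one row per colony (mouse_id, clone_id,
    colony_id, diameter_mm, fluor_signal, cell_count) and the mice table one
    row per mouse (mouse_id, clone_id, n_injected, harvest_hours). The round
    trip through :func:`read_fixtures` is lossless.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    colony_rows = []
    mouse_rows = []
    for b in cohort.burdens:
        mouse_rows.append(
            {"mouse_id": b.mouse_id, "clone_id": b.clone_id,
             "n_injected": b.n_injected, "harvest_hours": b.harvest_time}
        )
        for k, c in enumerate(b.colonies):
            colony_rows.append(
                {"mouse_id": b.mouse_id, "clone_id": b.clone_id, "colony_id": k,
                 "diameter_mm": c.diameter_mm, "fluor_signal": c.fluor_signal,
                 "cell_count": c.cell_count}
            )
    colonies_csv = directory / "colonies.csv"
    mice_csv = directory / "mice.csv"
    params_json = directory / "params.json"
    cols = ["mouse_id", "clone_id", "colony_id", "diameter_mm", "fluor_signal",
            "cell_count"]
    # %.17g keeps the text round trip bit-exact for float64
    pd.DataFrame(colony_rows, columns=cols).to_csv(
        colonies_csv, index=False, float_format="%.17g"
    )
    pd.DataFrame(
        mouse_rows, columns=["mouse_id", "clone_id", "n_injected", "harvest_hours"]
    ).to_csv(mice_csv, index=False, float_format="%.17g")
    params_json.write_text(json.dumps(cohort.params.to_dict(), indent=2))
    return {"colonies": colonies_csv, "mice": mice_csv, "params": params_json}


def read_fixtures(directory: str | Path) -> Cohort:
    """Read a cohort written by :func:`write_fixtures`."""
    directory = Path(directory)
    params = SimParams.from_dict(json.loads((directory / "params.json").read_text()))
    mice = pd.read_csv(directory / "mice.csv", float_precision="round_trip")
    colonies = pd.read_csv(directory / "colonies.csv", float_precision="round_trip")
    burdens = []
    for row in mice.itertuples(index=False):
        sub = colonies[colonies["mouse_id"] == row.mouse_id]
        cols = tuple(
            Colony(
                fluor_signal=float(c.fluor_signal),
                diameter_mm=None if pd.isna(c.diameter_mm) else float(c.diameter_mm),
                cell_count=None if pd.isna(c.cell_count) else float(c.cell_count),
            )
            for c in sub.sort_values("colony_id").itertuples(index=False)
        )
        burdens.append(
            LiverBurden(
                mouse_id=str(row.mouse_id),
                clone_id=str(row.clone_id),
                n_injected=int(row.n_injected),
                harvest_time=float(row.harvest_hours),
                colonies=cols,
            )
        )
    return Cohort(params=params, burdens=tuple(burdens))
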