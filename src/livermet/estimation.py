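"""Inverse procedures: recover Fc and Td from cohort data.

Estimators consume liver-burden tables in the same shape as the experimental
records (per-mouse colony counts and doses, per-colony fluorescence) whether
they come from real measurements or from :mod:`livermet.simulate`. The
parameter-recovery harness closes the loop: simulate cohorts at known
(Fc, Td), estimate them back, and report bias and relative error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .burden import LiverBurden, colonizing_fraction, colony_cells, doubling_time
from .calibration import CalibrationCurve, fit_calibration, pearson_correlation, CalibrationPoint, Modality
from .errors import UndefinedDoublingTimeError
from .simulate import SimParams, simulate_cohort

__all__ = [
    "RecoveryReport",
    "estimate_fc",
    "estimate_td",
    "fit_invitro_growth",
    "recover_params",
]


@dataclass(frozen=True)
class RecoveryReport:
    """Aggregate result of a simulate-then-estimate parameter-recovery study."""

    true_fc: float
    est_fc_mean: float
    est_fc_sd: float
    true_td: float
    est_td_mean: float
    est_td_sd: float
    n_mice: int
    n_replicates: int
    seed: int

    @property
    def fc_relative_error(self) -> float:
        return abs(self.est_fc_mean - self.true_fc) / self.true_fc

    @property
    def td_relative_error(self) -> float:
        return abs(self.est_td_mean - self.true_td) / self.true_td


def _sd(values: Sequence[float]) -> float:
    return float(np.std(values, ddof=1)) if len(values) > 1 else float("nan")


def estimate_fc(burdens: Sequence[LiverBurden]) -> tuple[float, float]:
    """Colonizing fraction: per-mouse tumors/dose, mean +/- SD across mice.

    The SD is NaN for a single mouse (flagged by convention, not an error).
    """
    if not burdens:
        raise ValueError("need at least one liver burden")
    fcs = [colonizing_fraction(b.n_tumors, b.n_injected) for b in burdens]
    return float(np.mean(fcs)), _sd(fcs)


def estimate_td(
    burdens: Sequence[LiverBurden],
    curve: CalibrationCurve,
    sample_size: int = 5,
    seed: int | None = None,
    all_colonies: bool = False,
) -> tuple[float, float]:
    """Doubling time from per-colony fluorescence, pooled across the cohort.

    From each liver up to ``sample_size`` colonies are drawn uniformly
    without replacement (mirroring quantification of a handful of
    representative colonies per liver); each sampled colony's cell number is
    inferred through the fluorescence standard curve and converted to a
    doubling time using that mouse's harvest time. Returns the pooled
    mean +/- sample SD in hours.
    """
    rng = np.random.default_rng(seed)
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
            if n >= 2:
                tds.append(doubling_time(n, b.harvest_time))
    if not tds:
        raise UndefinedDoublingTimeError(
            "no colony with >= 2 inferred cells; doubling time undefined"
        )
    return float(np.mean(tds)), _sd(tds)


def fit_invitro_growth(
    times: Sequence[float],
    signals: Sequence[float],
    normalize: bool = True,
) -> tuple[float, float]:
    """Doubling time from an in vitro growth curve by log-linear regression.

    Signals (proportional to live-cell number) are optionally normalized to
    the t = 0 reading, log2-transformed, and regressed on time; the slope is
    then divisions per hour and ``td = 1/slope``. Returns ``(td, r)`` where r
    is the Pearson coefficient of the log-linear fit. A non-growing culture
    (zero slope) yields ``td = inf``. Normalization does not change the
    slope, so the fitted td is invariant to overall signal scaling.
    """
    t = np.asarray(times, dtype=float)
    s = np.asarray(signals, dtype=float)
    if t.size != s.size:
        raise ValueError("times and signals must have equal length")
    if t.size < 3:
        raise ValueError("need at least 3 time points")
    if 0.0 not in t:
        raise ValueError("growth curve must include a t = 0 reading")
    if np.any(s <= 0):
        raise ValueError("signals must be positive")
    if normalize:
        s = s / s[t == 0.0][0]
    y = np.log2(s)
    slope, _ = np.polyfit(t, y, 1)
    if slope == 0 or np.ptp(y) == 0:
        return float("inf"), float("nan")
    r = pearson_correlation(t, y)
    return float(1.0 / slope), r


def recover_params(
    true_params: SimParams,
    n_mice: int,
    n_replicates: int,
    sample_size: int = 5,
    all_colonies: bool = False,
) -> RecoveryReport:
    """Simulate-then-estimate study of the (Fc, Td) estimators.

    Runs ``n_replicates`` independent cohorts of ``n_mice`` mice at the true
    parameters (replicate seeds derived deterministically from the params
    seed), estimates Fc and Td from each, and aggregates the estimates.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    fc_hats: list[float] = []
    td_hats: list[float] = []
    root = np.random.SeedSequence((true_params.seed, 2))
    rep_seeds = root.generate_state(2 * n_replicates, dtype=np.uint64) % (2**31)
    for r in range(n_replicates):
        p = replace(true_params, seed=int(rep_seeds[2 * r]))
        cohort = simulate_cohort(p, n_mice)
        fc_hat, _ = estimate_fc(cohort.burdens)
        td_hat, _ = estimate_td(
            cohort.burdens, p.fluor_curve,
            sample_size=sample_size, seed=int(rep_seeds[2 * r + 1]),
            all_colonies=all_colonies,
        )
        fc_hats.append(fc_hat)
        td_hats.append(td_hat)
    return RecoveryReport(
        true_fc=true_params.fc,
        est_fc_mean=float(np.mean(fc_hats)),
        est_fc_sd=_sd(fc_hats),
        true_td=true_params.td_mean,
        est_td_mean=float(np.mean(td_hats)),
        est_td_sd=_sd(td_hats),
        n_mice=n_mice,
        n_replicates=n_replicates,
        seed=true_params.seed,
    )
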