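#!/usr/bin/env python
"""Fit the cell-number/signal standard curves from simulated plates.

Simulates triplicated calibration plates at the standard plated densities
(0 to 1e5 cells/well) for both optical modalities with 5% multiplicative
measurement noise, fits the linear standard curves, and writes them for the
downstream steps. The linearity here (Pearson R >= 0.99) is what licenses
reading cell numbers off optical signal everywhere else in the analysis.
"""

import json
from pathlib import Path

from livermet import Modality, fit_calibration, generate_calibration_plate
from livermet.io import write_calibration_points
from livermet.simulate import DEFAULT_FLUOR_CURVE, DEFAULT_LUM_CURVE

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

SEED = 20260919

curves = {}
for modality, truth, seed in [
    (Modality.FLUORESCENCE, DEFAULT_FLUOR_CURVE, SEED),
    (Modality.LUMINESCENCE, DEFAULT_LUM_CURVE, SEED + 1),
]:
    plate = generate_calibration_plate(
        true_slope=truth.slope, true_intercept=truth.intercept,
        replicates=3, noise_cv=0.05, seed=seed, modality=modality,
    )
    write_calibration_points(plate, OUT / f"plate_{modality.value}.csv")
    curve = fit_calibration(plate)
    curve.to_json(OUT / f"curve_{modality.value}.json")
    curves[modality.value] = curve
    print(
        f"{modality.value:13s} slope={curve.slope:10.4g}  "
        f"intercept={curve.intercept:10.4g}  R={curve.pearson_r:.2f}  "
        f"(true slope {truth.slope:g}, n={curve.n_points})"
    )

assert all(c.pearson_r >= 0.99 for c in curves.values())
print(f"\nBoth modalities linear with R >= 0.99 -> {OUT}/curve_*.json")
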