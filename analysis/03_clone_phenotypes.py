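#!/usr/bin/env python
"""Estimate each clone's (Fc, Td, n_av, divisions) and classify its scenario.

Reads the simulated cohorts of step 02 and the fluorescence standard curve of
step 01, estimates the clone phenotypes exactly as one would from real burden
tables (5 sampled colonies per liver), and places each clone on the (Fc, Td)
plane: many-small (polymetastatic, P1-like), few-large (P2-like), or
few-small (oligometastatic-like).
"""

from pathlib import Path

import pandas as pd

from livermet import (
    CalibrationCurve,
    classify_phenotype,
    clone_phenotype,
    read_fixtures,
)
from livermet.simulate import SCENARIOS

ROOT = Path(__file__).resolve().parents[1] / "results"
SEED = 20260919

curve = CalibrationCurve.from_json(ROOT / "curve_fluorescence.json")

rows = []
for name in SCENARIOS:
    cohort = read_fixtures(ROOT / "cohorts" / name)
    ph = clone_phenotype(cohort.burdens, curve, sample_size=5, seed=SEED)
    scenario = classify_phenotype(ph)  # Fc 2e-5, Td 24.5 h thresholds
    rows.append(
        {"clone": name, "fc_mean": ph.fc_mean, "fc_sd": ph.fc_sd,
         "td_mean_h": ph.td_mean, "td_sd_h": ph.td_sd, "n_av": ph.n_av,
         "divisions": ph.divisions_mean, "n_mice": ph.n_mice,
         "scenario": scenario.value,
         "true_fc": cohort.params.fc, "true_td_h": cohort.params.td_mean}
    )
    print(
        f"{name}: Fc={ph.fc_mean:.2e}+/-{ph.fc_sd:.1e}  "
        f"Td={ph.td_mean:5.1f}+/-{ph.td_sd:.1f} h  n_av={ph.n_av:.3g}  "
        f"divisions={ph.divisions_mean:.1f}  -> {scenario.value}"
    )

df = pd.DataFrame(rows)
df.to_csv(ROOT / "clone_phenotypes.csv", index=False)
print(f"\nPhenotype table -> {ROOT / 'clone_phenotypes.csv'}")
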